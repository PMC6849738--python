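"""Slope computation, covariate rescaling, and AIC-based model selection."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely

from woodytrends.drivers import (
    akaike_table,
    dem_slope,
    enumerate_models,
    fit_all_models,
    fit_logistic,
    mean_slope_by_hexagon,
    recover_drivers,
    rescale_to_hexagons,
)
from woodytrends.hexgrid import make_hexgrid
from woodytrends.synthetic import DriverEffects, simulate_driver_records


def horn_slope_oracle(z, cell):
    """Straightforward per-cell Horn 3x3 with edge replication."""
    ny, nx = z.shape
    out = np.zeros_like(z, dtype=float)
    for r in range(ny):
        for c in range(nx):
            def v(rr, cc):
                return z[min(max(rr, 0), ny - 1), min(max(cc, 0), nx - 1)]
            a, b, cc_ = v(r - 1, c - 1), v(r - 1, c), v(r - 1, c + 1)
            d, f = v(r, c - 1), v(r, c + 1)
            g, h, i = v(r + 1, c - 1), v(r + 1, c), v(r + 1, c + 1)
            dzdx = ((cc_ + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
            dzdy = ((g + 2 * h + i) - (a + 2 * b + cc_)) / (8 * cell)
            out[r, c] = math.degrees(math.atan(math.hypot(dzdx, dzdy)))
    return out


class TestDemSlope:
    def test_flat_dem_zero_everywhere(self):
        assert (dem_slope(np.full((10, 10), 500.0), 90.0) == 0).all()

    def test_inclined_plane_recovers_analytic_angle(self):
        cell = 90.0
        x = np.arange(20) * cell
        z = np.tile(x * math.tan(math.radians(30.0)), (20, 1))
        s = dem_slope(z, cell)
        np.testing.assert_allclose(s[1:-1, 1:-1], 30.0, atol=1e-9)

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter

        z = gaussian_filter(rng.normal(0, 50, (15, 18)), 2.0) + 1000
        np.testing.assert_allclose(dem_slope(z, 90.0), horn_slope_oracle(z, 90.0),
                                   rtol=1e-12)

    def test_rotation_preserves_slope_magnitude(self):
        cell = 90.0
        x = np.arange(12) * cell
        plane = np.tile(x * 0.3, (12, 1))
        s1 = dem_slope(plane, cell)[2:-2, 2:-2]
        s2 = dem_slope(np.rot90(plane), cell)[2:-2, 2:-2]
        np.testing.assert_allclose(s1, np.rot90(s2), atol=1e-9)

    def test_degenerate_dem_fails(self):
        with pytest.raises(ValueError):
            dem_slope(np.ones((1, 30)), 90.0)


class TestMeanSlopeByHexagon:
    def _grid(self, nx=30, px=250.0):
        grid = make_hexgrid((0, 0, nx * px, nx * px), 2.0)
        cxy = (np.arange(nx) + 0.5) * px
        return grid, cxy

    def test_constant_raster_gives_constant(self):
        grid, cxy = self._grid()
        out = mean_slope_by_hexagon(np.full((30, 30), 12.5), grid, cxy, cxy)
        assert np.allclose(out.dropna(), 12.5)

    def test_split_raster_count_weighted_mean(self):
        grid, cxy = self._grid()
        slope = np.where(np.arange(30)[:, None] < 15, 10.0, 20.0) * np.ones((30, 30))
        out = mean_slope_by_hexagon(slope, grid, cxy, cxy)
        # enumeration oracle per hexagon
        from woodytrends.hexgrid import assign_points

        gx, gy = np.meshgrid(cxy, cxy)
        ids = assign_points(grid, gx.ravel(), gy.ravel())
        for hid in grid["hex_id"].sample(5, random_state=0):
            vals = slope.ravel()[ids == hid]
            if vals.size:
                assert out[hid] == pytest.approx(vals.mean())

    def test_hexagon_with_no_cells_missing(self):
        grid, _ = self._grid()
        cxy = np.array([125.0])  # one cell only
        out = mean_slope_by_hexagon(np.array([[3.0]]), grid, cxy, cxy)
        assert out.isna().sum() == len(grid) - 1


class TestRescaleToHexagons:
    def test_proportional_allocation_whole_containment(self):
        muni = pd.DataFrame(
            {"name": ["m1"], "geometry": [shapely.box(0, 0, 10_000, 10_000)]}
        )
        grid = make_hexgrid((0, 0, 10_000, 10_000), 2.0)
        out = rescale_to_hexagons(pd.Series({"m1": -300.0}), muni, grid)
        # hexagon fully inside gets value * (hex area / muni area)
        hex_area = grid["geometry"].iloc[0].area
        inner = [i for i, g in enumerate(grid["geometry"])
                 if g.within(muni["geometry"][0])]
        share = -300.0 * hex_area / 1e8
        assert out.iloc[inner[0]] == pytest.approx(share)

    def test_conservation_under_full_coverage(self):
        muni = pd.DataFrame(
            {
                "name": ["a", "b"],
                "geometry": [shapely.box(0, 0, 5_000, 10_000),
                             shapely.box(5_000, 0, 10_000, 10_000)],
            }
        )
        grid = make_hexgrid((0, 0, 10_000, 10_000), 2.0)
        vals = pd.Series({"a": -120.0, "b": 45.0})
        out = rescale_to_hexagons(vals, muni, grid)
        # hexagons cover the municipalities' union entirely
        assert out.sum() == pytest.approx(vals.sum(), rel=1e-9)

    def test_straddling_hexagon_weighted_by_exact_intersection(self):
        muni = pd.DataFrame(
            {
                "name": ["a", "b"],
                "geometry": [shapely.box(0, 0, 6_000, 10_000),
                             shapely.box(6_000, 0, 10_000, 10_000)],
            }
        )
        grid = make_hexgrid((0, 0, 10_000, 10_000), 3.0)
        vals = pd.Series({"a": 100.0, "b": -50.0})
        out = rescale_to_hexagons(vals, muni, grid)
        for i, g in enumerate(grid["geometry"]):
            ia = g.intersection(muni["geometry"][0]).area
            ib = g.intersection(muni["geometry"][1]).area
            expected = 100.0 * ia / muni["geometry"][0].area - 50.0 * ib / muni["geometry"][1].area
            if ia + ib > 0:
                assert out.iloc[i] == pytest.approx(expected, rel=1e-9)


class TestEnumerateModels:
    def test_five_terms_give_32_subsets(self):
        assert len(enumerate_models()) == 32

    def test_zero_terms_one_model(self):
        assert enumerate_models(()) == [()]

    def test_two_terms(self):
        assert enumerate_models(("A", "B")) == [(), ("A",), ("B",), ("A", "B")]

    def test_order_deterministic(self):
        assert enumerate_models() == enumerate_models()


class TestFitLogistic:
    def test_intercept_only_closed_form_with_printed_counts(self):
        """Bernoulli MLE on 479 losses / 829 gains: intercept log(829/479),
        AIC = -2[479 log(479/1308) + 829 log(829/1308)] + 2."""
        records = pd.DataFrame({"outcome": [0] * 479 + [1] * 829})
        fit = fit_logistic(records, ())
        assert fit.coefficients["Intercept"] == pytest.approx(
            math.log(829 / 479), rel=1e-6
        )
        expected_aic = -2 * (
            479 * math.log(479 / 1308) + 829 * math.log(829 / 1308)
        ) + 2
        assert fit.aic == pytest.approx(expected_aic, rel=1e-9)
        assert fit.k == 1

    def test_noise_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(4)
        n = 4000
        records = pd.DataFrame(
            {"outcome": rng.integers(0, 2, n), "dpop": rng.normal(0, 100, n)}
        )
        fit = fit_logistic(records, ("dpop",))
        assert abs(fit.coefficients["dpop"]) < 3 * fit.bse["dpop"]

    def test_parameter_count_tracks_dummy_columns(self):
        records, _ = simulate_driver_records(400, seed=1)
        k0 = fit_logistic(records, ()).k
        k1 = fit_logistic(records, ("slope",)).k
        kc = fit_logistic(records, ("country",)).k
        assert k1 - k0 == 1
        assert kc - k0 == records["country"].nunique() - 1

    def test_single_class_outcome_fails(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"outcome": [1, 1, 1]}), ())


class TestAkaikeTable:
    @staticmethod
    def _fake_fits(aics):
        from woodytrends.drivers import LogisticFit

        return [
            LogisticFit((f"t{i}",), a, 1, pd.Series(dtype=float),
                        pd.Series(dtype=float), True, False)
            for i, a in enumerate(aics)
        ]

    def test_single_model_weight_one(self):
        t = akaike_table(self._fake_fits([123.4]))
        assert t["weight"].iloc[0] == 1.0

    def test_hand_set_aics_closed_form_weights(self):
        t = akaike_table(self._fake_fits([100.0, 102.0, 110.0]))
        np.testing.assert_allclose(t["delta_aic"], [0.0, 2.0, 10.0])
        rel = np.array([1.0, math.exp(-1.0), math.exp(-5.0)])
        np.testing.assert_allclose(t["weight"], rel / rel.sum(), rtol=1e-12)

    def test_weights_sum_to_one_and_ratio_identity(self):
        rng = np.random.default_rng(5)
        t = akaike_table(self._fake_fits(list(200 + rng.uniform(0, 8, 12))))
        assert t["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        w = t["weight"].to_numpy()
        d = t["delta_aic"].to_numpy()
        for i in range(1, len(t)):
            assert w[0] / w[i] == pytest.approx(math.exp(d[i] / 2.0), rel=1e-9)

    def test_ranking_invariant_to_constant_shift(self):
        aics = [150.0, 151.3, 149.2, 160.0]
        t1 = akaike_table(self._fake_fits(aics))
        t2 = akaike_table(self._fake_fits([a + 37.0 for a in aics]))
        assert list(t1["model"]) == list(t2["model"])
        np.testing.assert_allclose(t1["weight"], t2["weight"], rtol=1e-12)


class TestModelSelection:
    def test_nested_model_aic_bound(self):
        """logL is monotone under nesting: AIC(sub) >= AIC(parent) - 2*extra."""
        records, _ = simulate_driver_records(800, seed=6)
        fits, _ = fit_all_models(records, ("dpop", "slope"))
        by_terms = {f.terms: f for f in fits}
        parent = by_terms[("dpop", "slope")]
        for sub_terms in [(), ("dpop",), ("slope",)]:
            sub = by_terms[sub_terms]
            extra = parent.k - sub.k
            assert sub.aic >= parent.aic - 2 * extra - 1e-6

    def test_recover_generating_signs(self):
        records, truth = simulate_driver_records(1500, seed=7)
        report = recover_drivers(records, truth)
        assert report["dpop_sign_recovered"]
        assert report["dpop_within_3se"]

    def test_recovery_deterministic_given_seed(self):
        r1 = recover_drivers(*simulate_driver_records(600, seed=8))
        r2 = recover_drivers(*simulate_driver_records(600, seed=8))
        assert r1["dpop_coef_fitted"] == r2["dpop_coef_fitted"]
        assert r1["generating_delta_aic"] == r2["generating_delta_aic"]

    def test_null_generator_keeps_intercept_competitive(self):
        eff = DriverEffects(
            intercept=0.2, country_effects=(0.0, 0.0, 0.0),
            elev_zone_effects=(0.0,) * 7, dpop_coef=0.0,
        )
        hits = 0
        for seed in range(5):
            records, _ = simulate_driver_records(400, eff, seed=seed)
            _, table = fit_all_models(records, ("slope", "dntl", "dpop"))
            row = table[table["terms"].apply(lambda t: t == ())]
            if float(row["delta_aic"].iloc[0]) < 2.0:
                hits += 1
        assert hits >= 3  # intercept-only within dAIC 2 in most null replicates
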