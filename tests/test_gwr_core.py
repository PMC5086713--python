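"""Kernels, distances, local weighted least squares and bandwidth search."""

import datetime as dt

import numpy as np
import pytest

from gwrpm25.data_model import ModelRow, RunConfig
from gwrpm25.gwr_core import (
    SingularFitError,
    adaptive_bandwidth_km,
    bisquare_weight,
    design_matrix,
    fit_gwr,
    haversine_km,
    kernel_weights,
    local_wls,
    pairwise_km,
    predict_gwr,
    select_bandwidth,
)

DAY = dt.date(2015, 4, 10)


from helpers import rows_from_arrays as _rows_from_arrays, synthetic_rows as _random_rows


class TestDistance:
    def test_zero_for_identical_points(self):
        assert haversine_km((101.0, 34.0), (101.0, 34.0)) == 0.0

    def test_one_degree_meridian_arc(self):
        # closed form 2*pi*R/360 with R = 6371 km
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(111.195, abs=1e-3)
        assert haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(111.195, abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.uniform([70, 5], [140, 50], (2, 2))
            assert haversine_km(a, b) == pytest.approx(haversine_km(b, a), rel=1e-12)


class TestKernels:
    def test_bisquare_values(self):
        b = 100.0
        assert bisquare_weight(0.0, b) == 1.0
        assert bisquare_weight(b / 2, b) == pytest.approx(0.5625)
        assert bisquare_weight(b, b) == 0.0
        assert bisquare_weight(2 * b, b) == 0.0

    def test_nonpositive_bandwidth_raises(self):
        with pytest.raises(ValueError):
            bisquare_weight(1.0, 0.0)

    def test_compact_support(self):
        d = np.linspace(0, 300, 31)
        w = kernel_weights(d, 150.0, "bisquare")
        assert (w[d >= 150.0] == 0).all()
        assert (w[d < 150.0] > 0).all()


class TestAdaptiveBandwidth:
    def test_kth_distance(self):
        assert adaptive_bandwidth_km([1.0, 2.0, 3.0, 4.0], k=3) == 3.0

    def test_k_equals_n_gives_max(self):
        assert adaptive_bandwidth_km([4.0, 1.0, 9.0, 2.0], k=4) == 9.0

    def test_ties_at_kth(self):
        # tied points sit exactly at the bandwidth and get bisquare weight 0
        b = adaptive_bandwidth_km([1.0, 3.0, 3.0, 5.0], k=2)
        assert b == 3.0
        assert bisquare_weight(3.0, b) == 0.0

    def test_underdetermined_k_raises_with_fitting_floor(self):
        with pytest.raises(ValueError, match="under-determined"):
            adaptive_bandwidth_km([1.0] * 10, k=5, min_k=8)

    def test_k_beyond_points_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            adaptive_bandwidth_km([1.0, 2.0], k=3)


class TestLocalWLS:
    def test_uniform_weights_match_ols_oracle(self):
        """With every weight equal, the local fit is global OLS (statsmodels)."""
        import statsmodels.api as sm

        rows = _random_rows(100, seed=1)
        X, y, _ = design_matrix(rows)
        oracle = sm.OLS(y, X).fit().params
        beta, _ = local_wls(rows, (102.0, 34.0), np.inf, "uniform")
        np.testing.assert_allclose(beta, oracle, rtol=1e-8)

    def test_exact_linear_data_gives_r2_one(self):
        beta_true = np.array([30.0, 80.0, -1.5, 0.3, -4e-4, -2.0])
        rows = _random_rows(60, seed=2, noise=0.0, beta=beta_true)
        beta, r2 = local_wls(rows, (102.0, 34.0), 1e4, "bisquare")
        np.testing.assert_allclose(beta, beta_true, rtol=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_is_singular(self):
        rows = _random_rows(50, seed=3)
        X, y, ll = design_matrix(rows)
        X[:, 5] = X[:, 3]  # ws duplicates st
        dup = _rows_from_arrays(X, y, ll)
        with pytest.raises(SingularFitError):
            local_wls(dup, (102.0, 34.0), np.inf, "uniform")

    def test_permutation_invariance(self):
        rows = _random_rows(80, seed=4)
        rng = np.random.default_rng(0)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        b1, r1 = local_wls(rows, (102.0, 34.0), 200.0, "bisquare")
        b2, r2 = local_wls(shuffled, (102.0, 34.0), 200.0, "bisquare")
        np.testing.assert_allclose(b1, b2, rtol=1e-10)
        assert r1 == pytest.approx(r2, rel=1e-10)

    def test_duplicated_rows_leave_fit_unchanged(self):
        rows = _random_rows(60, seed=5)
        b1, r1 = local_wls(rows, (102.0, 34.0), 250.0, "bisquare")
        b2, r2 = local_wls(rows + rows, (102.0, 34.0), 250.0, "bisquare")
        np.testing.assert_allclose(b1, b2, rtol=1e-10)
        assert r1 == pytest.approx(r2, rel=1e-10)

    def test_zero_precip_neighbourhood_pins_coefficient(self):
        """Identically-zero local precipitation fixes that slope at 0 rather
        than failing the whole fit."""
        rows = _random_rows(60, seed=6)
        X, y, ll = design_matrix(rows)
        X[:, 2] = 0.0
        dry = _rows_from_arrays(X, y, ll)
        beta, _ = local_wls(dry, (102.0, 34.0), np.inf, "uniform")
        assert beta[2] == 0.0


class TestBandwidthSearch:
    def test_singleton_range(self):
        rows = _random_rows(60, seed=7)
        assert select_bandwidth(rows, "bisquare", [15]) == 15

    def test_golden_section_matches_exhaustive(self):
        """On a 60-row instance with a well-behaved LOO score the golden
        search finds the exhaustive minimiser."""
        rows = _random_rows(60, seed=8, noise=8.0)
        k_golden = select_bandwidth(rows, "bisquare", (10, 59))
        k_exh = select_bandwidth(rows, "bisquare", (10, 59), exhaustive=True)
        assert k_golden == k_exh

    def test_flat_truth_low_noise_favours_wide_bandwidth(self, flat_rows):
        """Spatially constant true coefficients: more neighbours always help,
        so k* lands in the top quartile of the range."""
        k = select_bandwidth(flat_rows, "bisquare", (10, len(flat_rows) - 1))
        lo, hi = 10, len(flat_rows) - 1
        assert k >= lo + 0.75 * (hi - lo)


@pytest.fixture(scope="module")
def flat_rows():
    import dataclasses

    from gwrpm25 import pipeline
    from gwrpm25.synthetic_scene import SceneConfig, generate_scene

    cfg = dataclasses.replace(
        SceneConfig.noiseless(
            lon_min=100.0, lon_max=103.0, lat_min=33.0, lat_max=36.0, n_stations=90, n_clusters=3
        ),
        noise_sd=2.0,
    )
    scene = generate_scene(cfg, seed=13, dates=[DAY])
    return pipeline.scene_model_rows(scene)[0][DAY]


class TestFitPredict:
    def test_fit_below_row_floor_raises(self):
        rows = _random_rows(10, seed=9)
        with pytest.raises(ValueError, match="floor"):
            fit_gwr(rows, RunConfig(min_rows=20), k=9)

    def test_fit_stores_shapes_and_bounds(self, small_rows):
        rows_by_day, config = small_rows
        rows = next(iter(rows_by_day.values()))
        fit = fit_gwr(rows, config, k=45)
        assert fit.betas.shape == (len(rows), 6)
        assert (fit.local_r2 <= 1 + 1e-12).all()
        assert fit.k == 45

    def test_prediction_moves_toward_observation_when_row_included(self):
        """Adding the target's own row pulls the local fit toward its y."""
        rows = _random_rows(80, seed=10, noise=10.0)
        config = RunConfig(k_min=40, singular_fallback="missing")
        target = rows[0]
        rest = rows[1:]
        pred_excl = predict_gwr(rest, config, [target], k=40)[0]
        pred_incl = predict_gwr(rows, config, [target], k=40)[0]
        assert np.isfinite(pred_excl) and np.isfinite(pred_incl)
        y = target.revised_pm25
        assert abs(pred_incl - y) <= abs(pred_excl - y) + 1e-9

    def test_constant_coefficient_noiseless_prediction_exact(self, noiseless_scene):
        from gwrpm25 import pipeline

        config = pipeline.config_for_scene(noiseless_scene)
        day = noiseless_scene.dates[0]
        rows = pipeline.scene_model_rows(noiseless_scene, config)[0][day]
        pred = predict_gwr(rows, config, rows, k=60)
        y = np.array([r.revised_pm25 for r in rows])
        np.testing.assert_allclose(pred, y, rtol=1e-8)

    def test_ols_limit_every_location(self):
        """Infinite-bandwidth uniform weights reproduce global OLS at every
        calibration point."""
        rows = _random_rows(100, seed=11)
        X, y, ll = design_matrix(rows)
        beta_global = np.linalg.lstsq(X, y, rcond=None)[0]
        for target in [(100.5, 32.5), (103.9, 35.9), (102.0, 34.0)]:
            beta, _ = local_wls(rows, target, np.inf, "uniform")
            np.testing.assert_allclose(beta, beta_global, rtol=1e-8)
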