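"""Scene-generator statistical structure and determinism."""

import dataclasses
import datetime as dt
import math

import numpy as np
import pytest
from scipy import stats

from gwrpm25.physical_corrections import revise_pm25
from gwrpm25.synthetic_scene import (
    COEF_NAMES,
    SceneConfig,
    default_dates,
    generate_scene,
    make_aod_granules,
    make_coefficient_surfaces,
    make_column_aod,
    make_meteorology,
    make_station_network,
    neighbor_mean_bound,
)

DAY = dt.date(2015, 4, 10)

SMALL = dict(lon_min=100.0, lon_max=103.0, lat_min=33.0, lat_max=36.0, n_stations=50)


class TestCoefficientSurfaces:
    def test_zero_amplitude_gives_exact_means(self):
        cfg = SceneConfig(coef_amps=(0.0,) * 6, **SMALL)
        truth = make_coefficient_surfaces(cfg, seed=1)
        for i, name in enumerate(COEF_NAMES):
            np.testing.assert_array_equal(truth.surfaces[name].values, cfg.coef_means[i])

    def test_deterministic_from_config_and_seed(self):
        cfg = SceneConfig(**SMALL)
        a = make_coefficient_surfaces(cfg, seed=5)
        b = make_coefficient_surfaces(cfg, seed=5)
        for name in COEF_NAMES:
            np.testing.assert_array_equal(a.surfaces[name].values, b.surfaces[name].values)

    def test_different_seed_differs(self):
        cfg = SceneConfig(**SMALL)
        a = make_coefficient_surfaces(cfg, seed=5)
        b = make_coefficient_surfaces(cfg, seed=6)
        assert not np.array_equal(a.surfaces["beta1"].values, b.surfaces["beta1"].values)

    def test_smoothness_bound_from_components(self):
        """Cell-vs-4-neighbour discrepancy never exceeds the closed-form
        bound implied by the sinusoid wavelengths."""
        cfg = SceneConfig(**SMALL)
        truth = make_coefficient_surfaces(cfg, seed=2)
        for name in COEF_NAMES:
            fld = truth.surfaces[name]
            v = fld.values
            nbr = (v[:-2, 1:-1] + v[2:, 1:-1] + v[1:-1, :-2] + v[1:-1, 2:]) / 4.0
            disc = np.abs(v[1:-1, 1:-1] - nbr).max()
            bound = neighbor_mean_bound(truth.components[name], fld.dlon, fld.dlat)
            assert disc <= bound + 1e-12

    def test_nonpositive_correlation_length_rejected(self):
        with pytest.raises(Exception):
            SceneConfig(coef_corr_len_deg=0.0, **SMALL)


class TestStationNetwork:
    def test_count_and_domain(self):
        cfg = SceneConfig(**SMALL)
        st_list = make_station_network(cfg, seed=3)
        assert len(st_list) == cfg.n_stations
        for _, lon, lat in st_list:
            assert cfg.lon_min <= lon <= cfg.lon_max
            assert cfg.lat_min <= lat <= cfg.lat_max

    def test_unclustered_uniformity_chi_square(self):
        """clustering=0 passes a 4x4 occupancy chi-square test at alpha=0.01."""
        cfg = SceneConfig(clustering=0.0, n_stations=2000, **{k: v for k, v in SMALL.items() if k != "n_stations"})
        pts = np.array([(lon, lat) for _, lon, lat in make_station_network(cfg, seed=4)])
        counts, _, _ = np.histogram2d(
            pts[:, 0], pts[:, 1],
            bins=[np.linspace(cfg.lon_min, cfg.lon_max, 5), np.linspace(cfg.lat_min, cfg.lat_max, 5)],
        )
        _, p = stats.chisquare(counts.ravel())
        assert p > 0.01

    def test_clustering_raises_occupancy_variance(self):
        base = {k: v for k, v in SMALL.items() if k != "n_stations"}
        occ = {}
        for c in (0.0, 0.9):
            cfg = SceneConfig(clustering=c, n_stations=2000, **base)
            pts = np.array([(lon, lat) for _, lon, lat in make_station_network(cfg, seed=4)])
            counts, _, _ = np.histogram2d(
                pts[:, 0], pts[:, 1],
                bins=[np.linspace(cfg.lon_min, cfg.lon_max, 5), np.linspace(cfg.lat_min, cfg.lat_max, 5)],
            )
            occ[c] = counts.ravel().var()
        assert occ[0.9] > occ[0.0]

    def test_density_ceiling(self):
        with pytest.raises(Exception, match="ceiling"):
            SceneConfig(n_stations=6000, **{k: v for k, v in SMALL.items() if k != "n_stations"})


class TestMeteorology:
    def test_degenerate_pblh_is_unit(self):
        cfg = SceneConfig(pblh_mu=0.0, pblh_sigma=0.0, **SMALL)
        met = make_meteorology(cfg, DAY, seed=1)
        np.testing.assert_array_equal(met["pblh"].values, 1.0)

    def test_pblh_positive_rh_in_range(self):
        cfg = SceneConfig(**SMALL)
        met = make_meteorology(cfg, DAY, seed=1)
        assert (met["pblh"].values > 0).all()
        assert (met["rh"].values >= 0).all()
        assert (met["rh"].values <= cfg.rh_cap).all()

    def test_rh_mean_matches_configured_marginal(self):
        """Sample mean over >=10^4 cells within 3 SE of the Weibull mean."""
        cfg = SceneConfig(met_cell_deg=0.1)  # full-size domain: >10^4 cells
        met = make_meteorology(cfg, DAY, seed=2)
        rh = met["rh"].values.ravel()
        assert rh.size >= 10_000
        target = cfg.rh_weibull_scale * math.gamma(1 + 1 / cfg.rh_weibull_shape)
        se = rh.std() / math.sqrt(rh.size)
        assert abs(rh.mean() - target) <= 3 * se

    def test_bimodal_pressure_two_component_mixture(self):
        """A 2-component Gaussian mixture separates two pressure modes and
        beats one component by BIC."""
        from sklearn.mixture import GaussianMixture

        cfg = SceneConfig(met_cell_deg=0.1, bimodal_pressure=True)
        ps = make_meteorology(cfg, DAY, seed=3)["ps"].values.reshape(-1, 1)
        g1 = GaussianMixture(1, random_state=0).fit(ps)
        g2 = GaussianMixture(2, random_state=0).fit(ps)
        assert g2.bic(ps) < g1.bic(ps)
        order = np.argsort(g2.means_.ravel())
        mu = g2.means_.ravel()[order]
        sig = np.sqrt(g2.covariances_.ravel())[order]
        w = g2.weights_[order]
        # two genuinely populated modes, separated well beyond the narrower
        # component's spread (the plateau-lowland transition broadens one)
        assert w.min() > 0.15
        assert mu[1] - mu[0] > 3 * sig.min()

    def test_invalid_rh_parameters_rejected_at_config_time(self):
        with pytest.raises(Exception, match="RH"):
            SceneConfig(rh_weibull_scale=90.0, **SMALL)


class TestObservations:
    def test_noiseless_identity(self):
        """noise=0, jitter=0: the recorded value is exactly the linear
        predictor pushed through the inverse hygroscopic correction."""
        cfg = SceneConfig.noiseless(**SMALL)
        scene = generate_scene(cfg, seed=5, dates=[DAY])
        truth = {t.station_id: t for t in scene.truth_rows[DAY]}
        for rec in scene.records:
            t = truth[rec.station_id]
            x = np.array([1.0, t.revised_aod, t.last_prec, t.st, t.ps, t.ws])
            beta = scene.truth.beta_at(rec.lon, rec.lat)
            expected_dry = max(float(x @ beta), 0.0) * (1 - t.rh / 100.0)
            assert rec.pm25 == pytest.approx(expected_dry, rel=1e-10, abs=1e-12)
            # and the revised scale round-trips through the correction
            assert revise_pm25(rec.pm25, t.rh) == pytest.approx(t.revised_pm25, rel=1e-10)

    def test_dry_is_revised_scaled_by_humidity(self):
        """Recorded dry values are the revised response shrunk by
        (1 - RH/100); at RH -> 0 the two scales coincide."""
        cfg = SceneConfig.noiseless(**SMALL)
        scene = generate_scene(cfg, seed=6, dates=[DAY])
        for t in scene.truth_rows[DAY][:20]:
            assert t.pm25 == pytest.approx(t.revised_pm25 * (1 - t.rh / 100.0), rel=1e-12)
            assert revise_pm25(t.pm25, 0.0) == pytest.approx(t.pm25)

    def test_noise_is_centred(self):
        """Mean deviation of recorded from noiseless dry values ~ 0 within
        3 standard errors over >= 10^4 records."""
        cfg = SceneConfig(hour_jitter_sd=0.0, **{**SMALL, "n_stations": 400})
        dates = default_dates()[:13]  # 400 stations x 13 days x 2 hourly records
        scene = generate_scene(cfg, seed=7, dates=dates)
        assert len(scene.records) >= 10_000
        devs = []
        for d in dates:
            truth = {t.station_id: t for t in scene.truth_rows[d]}
            for rec in scene.records:
                if rec.date != d:
                    continue
                t = truth[rec.station_id]
                devs.append(rec.pm25 - t.pm25)
        devs = np.array(devs)
        se = devs.std() / math.sqrt(len(devs))
        assert abs(devs.mean()) <= 3 * se

    def test_full_determinism(self):
        cfg = SceneConfig(**SMALL)
        s1 = generate_scene(cfg, seed=9, dates=[DAY])
        s2 = generate_scene(cfg, seed=9, dates=[DAY])
        assert s1.records == s2.records
        np.testing.assert_array_equal(s1.fused[DAY].values, s2.fused[DAY].values)
        np.testing.assert_array_equal(
            s1.granules[DAY][0].qa, s2.granules[DAY][0].qa
        )


@pytest.fixture(scope="module")
def scene_inputs():
    cfg = SceneConfig(**SMALL)
    met = make_meteorology(cfg, DAY, seed=8)
    column = make_column_aod(cfg, met["pblh"], DAY, seed=8)
    return cfg, met, column


class TestGranules:
    def test_noiseless_dt_equals_column(self, scene_inputs):
        cfg, met, column = scene_inputs
        clean = dataclasses.replace(
            cfg, dt_noise_sd=0.0, bright_fraction=0.0, dt_qa_probs=(0, 0, 0, 1.0), db_qa_probs=(0, 0, 0, 1.0)
        )
        dt_g, _ = make_aod_granules(column, clean, DAY, seed=8)
        np.testing.assert_allclose(dt_g.field.values, column.values, rtol=1e-12)
        assert not dt_g.field.mask.any()

    def test_bright_fraction_binomial(self):
        """DT missing fraction 0.30 +- 0.02 over >= 10^4 cells."""
        cfg = SceneConfig(bright_fraction=0.3)  # full-size fine grid
        met = make_meteorology(cfg, DAY, seed=9)
        column = make_column_aod(cfg, met["pblh"], DAY, seed=9)
        dt_g, _ = make_aod_granules(column, cfg, DAY, seed=9)
        assert dt_g.field.mask.size >= 10_000
        frac = dt_g.field.mask.mean()
        assert abs(frac - 0.30) <= 0.02

    def test_bright_cells_have_db_coverage(self, scene_inputs):
        cfg, met, column = scene_inputs
        bright_cfg = dataclasses.replace(cfg, bright_fraction=0.4)
        dt_g, db_g = make_aod_granules(column, bright_cfg, DAY, seed=10)
        assert dt_g.field.mask.any()
        assert not db_g.field.mask.any()  # DB covers the whole (incl. bright) scene

    def test_db_is_block_average(self, scene_inputs):
        cfg, met, column = scene_inputs
        clean = dataclasses.replace(cfg, db_noise_sd=0.0)
        _, db_g = make_aod_granules(column, clean, DAY, seed=11)
        # brute-force average of fine cells whose centers fall in DB cell (0, 0)
        flons, flats = column.lons(), column.lats()
        sel_lon = (flons >= db_g.field.origin_lon - 0.05) & (flons < db_g.field.origin_lon + 0.05)
        sel_lat = (flats >= db_g.field.origin_lat - 0.05) & (flats < db_g.field.origin_lat + 0.05)
        expected = column.values[np.ix_(sel_lat, sel_lon)].mean()
        assert db_g.field.values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_mask_fraction_one_rejected(self):
        with pytest.raises(Exception, match="bright_fraction"):
            SceneConfig(bright_fraction=1.0, **SMALL)
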