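"""Synthetic study scenes for the AOD-PM2.5 estimation pipeline.

A scene emulates one season-spanning campaign over a regular lat-lon
domain: smooth spatially varying regression-coefficient surfaces (the
"truth" the GWR should recover), an unevenly clustered station network,
per-day meteorological fields whose marginals follow the families seen in
national reanalysis summaries (log-normal PBLH, Weibull-like RH and
temperature, optionally bimodal pressure driven by a plateau/lowland
elevation contrast), and paired Dark Target 3 km / Deep Blue 10 km AOD
granules with QA flags and bright-surface missingness.

Smooth fields are superpositions of random-phase low-frequency sinusoids
rather than Gaussian-process draws: evaluation is exact and cheap, the
scene is bit-reproducible from (config, seed), and each component carries
an explicit wavelength so discrete-smoothness bounds can be computed in
closed form.  Marginal shapes are imposed by rank-mapping the smooth field
through the target family's quantile function, which preserves spatial
smoothness (a monotone transform of a smooth field).

Recorded station PM2.5 inverts the model's own physical corrections:
revised PM2.5 is the linear predictor evaluated with the truth
coefficients plus Gaussian noise on the revised (humidity-corrected)
scale, and the recorded dry value is revised x (1 - RH/100).  Regressors
at stations are computed with the same access rules the pipeline uses
(AOD by containing pixel, meteorology by bilinear interpolation), so a
noiseless constant-coefficient scene closes the loop exactly.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .aod_fusion import apply_qa_filter, fuse_dt_db, regrid_db_to_fine
from .data_model import AODGranule, GriddedField, ModelRow, StationRecord, ValidationError
from .integration import (
    bilinear_at,
    overpass_hours_beijing,
    prev_day_precip,
    zone_offset,
)
from .physical_corrections import dry_pm25

__all__ = [
    "HarmonicComponent",
    "SceneConfig",
    "SceneTruth",
    "Scene",
    "default_dates",
    "make_coefficient_surfaces",
    "make_station_network",
    "make_meteorology",
    "make_aod_granules",
    "make_observations",
    "generate_scene",
    "neighbor_mean_bound",
]

COEF_NAMES = ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5")


@dataclass(frozen=True)
class HarmonicComponent:
    """One sinusoid a*sin(kx*lon + ky*lat + phase); k in radians/degree."""

    amp: float
    kx: float
    ky: float
    phase: float


def _sample_components(rng, amplitude: float, corr_len: float, n_comp: int = 32):
    """Random-phase sinusoids with wavelengths in [2, 6] correlation lengths.

    Per-component amplitude amplitude*sqrt(2/n) makes the superposition's
    spatial RMS approximately ``amplitude``.
    """
    if corr_len <= 0:
        raise ValidationError("correlation length must be positive")
    if amplitude == 0:
        return []
    lam = rng.uniform(2 * corr_len, 6 * corr_len, n_comp)
    theta = rng.uniform(0, 2 * math.pi, n_comp)
    phase = rng.uniform(0, 2 * math.pi, n_comp)
    a = amplitude * math.sqrt(2.0 / n_comp)
    return [
        HarmonicComponent(a, 2 * math.pi / l * math.cos(t), 2 * math.pi / l * math.sin(t), p)
        for l, t, p in zip(lam, theta, phase)
    ]


def _eval_components(comps, lon2, lat2):
    out = np.zeros_like(lon2, dtype=float)
    for c in comps:
        out += c.amp * np.sin(c.kx * lon2 + c.ky * lat2 + c.phase)
    return out


def neighbor_mean_bound(comps, dlon: float, dlat: float) -> float:
    """Exact bound on |f(cell) - mean of its 4 axis neighbours|.

    For a sinusoid with wavevector (kx, ky) on a grid with spacing
    (dlon, dlat), f minus the E/W/N/S neighbour mean equals
    f * (1 - (cos(kx*dlon) + cos(ky*dlat))/2), so the component amplitudes
    bound the discrepancy exactly.
    """
    return float(
        sum(
            c.amp * (1.0 - 0.5 * (math.cos(c.kx * dlon) + math.cos(c.ky * dlat)))
            for c in comps
        )
    )


@dataclass
class SceneConfig:
    """Scene parameters; the defaults define the reference study scene.

    A 10 x 10 degree domain, 0.03/0.1 degree AOD grids (preserving the
    MODIS 3 km : 10 km resolution ratio), 400 unevenly clustered stations,
    30 days spread over the four meteorological seasons, and noise of
    10 ug/m3 (sd) on the revised-PM2.5 scale.
    """

    lon_min: float = 95.0
    lon_max: float = 105.0
    lat_min: float = 30.0
    lat_max: float = 40.0
    fine_cell_deg: float = 0.03
    coarse_cell_deg: float = 0.1
    met_cell_deg: float = 0.5
    beta_cell_deg: float = 0.25

    n_stations: int = 400
    clustering: float = 0.7  # fraction of stations drawn around cluster centers
    n_clusters: int = 6
    cluster_sd_deg: float = 0.6
    max_stations: int = 5000

    # truth coefficient surfaces: mean and perturbation RMS, scaled so each
    # term's coefficient variation contributes a comparable few ug/m3 of
    # spatial response variance (amplitudes multiply regressors of order
    # 0.6, 1, 290 K, 9e4 Pa and 3 m/s respectively)
    coef_means: tuple = (30.0, 80.0, -1.5, 0.3, -4.0e-4, -2.0)
    coef_amps: tuple = (10.0, 30.0, 0.5, 0.03, 5.0e-5, 0.5)
    coef_corr_len_deg: float = 5.0

    # meteorology marginals
    pblh_mu: float = math.log(0.9)  # log-km
    pblh_sigma: float = 0.35
    rh_weibull_shape: float = 4.0
    rh_weibull_scale: float = 55.0  # percent
    st_weibull_shape: float = 2.2
    st_weibull_scale: float = 17.0  # K above st_base
    st_base: float = 275.0
    st_season_offset: tuple = (-12.0, 0.0, 8.0, -2.0)  # DJF, MAM, JJA, SON
    bimodal_pressure: bool = True
    wind_mean: tuple = (1.0, 0.5)  # m/s
    wind_sd: float = 2.5
    precip_threshold: float = 0.8  # latent-z threshold; ~20% wet cells
    precip_scale_mm: float = 12.0
    met_corr_len_deg: float = 2.0

    # AOD scene
    raod_sigma: float = 0.5  # log-sd of the revised-AOD field
    raod_scale: float = 0.55  # median revised AOD (per km)
    # aerosol varies at plume/urban scales far finer than 1-deg meteorology;
    # sub-degree correlation also keeps the AOD term locally identifiable
    aod_corr_len_deg: float = 0.5
    bright_fraction: float = 0.25
    dt_qa_probs: tuple = (0.05, 0.10, 0.15, 0.70)
    db_qa_probs: tuple = (0.05, 0.10, 0.25, 0.60)
    dt_noise_sd: float = 0.02
    db_noise_sd: float = 0.02

    noise_sd: float = 10.0  # ug/m3 on the revised scale
    hour_jitter_sd: float = 3.0  # ug/m3 on the dry scale, per hourly record
    rh_cap: float = 95.0
    n_harmonics: int = 32

    def __post_init__(self) -> None:
        if not (0 <= self.bright_fraction < 1):
            raise ValidationError("bright_fraction must be in [0, 1)")
        if self.coef_corr_len_deg <= 0 or self.met_corr_len_deg <= 0:
            raise ValidationError("correlation lengths must be positive")
        if self.n_stations < 1:
            raise ValidationError("need at least one station")
        if self.n_stations > self.max_stations:
            raise ValidationError(
                f"{self.n_stations} stations exceeds density ceiling {self.max_stations}"
            )
        for probs in (self.dt_qa_probs, self.db_qa_probs):
            if len(probs) != 4 or abs(sum(probs) - 1) > 1e-9:
                raise ValidationError("QA probabilities must be 4 values summing to 1")
        # reject parameter sets that would put RH at/above 100 or PBLH at 0
        if self.rh_weibull_shape > 0:
            q = stats.weibull_min.ppf(
                0.9999, self.rh_weibull_shape, scale=self.rh_weibull_scale
            )
            if q >= 100:
                raise ValidationError(
                    f"RH Weibull parameters reach {q:.1f}% (>= 100) at the 0.9999 quantile"
                )
        if not (0 < self.rh_cap < 100):
            raise ValidationError("rh_cap must be in (0, 100)")

    @classmethod
    def noiseless(cls, **kw) -> "SceneConfig":
        """Exact-closure preset: constant coefficients, no noise of any kind."""
        base = dict(
            coef_amps=(0.0,) * 6,
            noise_sd=0.0,
            hour_jitter_sd=0.0,
            dt_noise_sd=0.0,
            db_noise_sd=0.0,
            bright_fraction=0.0,
            dt_qa_probs=(0.0, 0.0, 0.0, 1.0),
            db_qa_probs=(0.0, 0.0, 0.0, 1.0),
        )
        base.update(kw)
        return cls(**base)


@dataclass
class SceneTruth:
    """Truth coefficient surfaces beta0..beta5 plus the generative noise sd."""

    surfaces: dict  # name -> GriddedField
    components: dict  # name -> list[HarmonicComponent]
    noise_sd: float
    seed: int

    def beta_at(self, lon: float, lat: float) -> np.ndarray:
        return np.array(
            [bilinear_at(self.surfaces[n], lon, lat) for n in COEF_NAMES]
        )


@dataclass
class Scene:
    """A complete generated scene: inputs, intermediates and truth."""

    config: SceneConfig
    seed: int
    truth: SceneTruth
    stations: list  # (station_id, lon, lat)
    dates: list
    met: dict  # date -> {var: GriddedField}
    precip: dict  # date -> GriddedField (includes day before each study day)
    granules: dict  # date -> (dt AODGranule, db AODGranule)
    fused: dict  # date -> GriddedField
    column_aod: dict  # date -> noiseless fine-grid column AOD GriddedField
    records: list  # StationRecord
    truth_rows: dict  # date -> list[ModelRow] (noiseless)


def default_dates(year: int = 2015) -> list[_dt.date]:
    """30 study days: 8 each in Jan/Apr, 7 each in Jul/Oct (all four seasons)."""
    days = []
    for month, n in ((1, 8), (4, 8), (7, 7), (10, 7)):
        days += [_dt.date(year, month, 10 + i) for i in range(n)]
    return days


# ---------------------------------------------------------------------------
# grids


def _grid(cfg: SceneConfig, cell: float, pad_cells: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinate vectors covering the domain (optionally padded)."""
    # ceiling so the cells cover the domain even when the span is not an
    # exact multiple of the cell size (e.g. 10 deg / 0.03 deg)
    nlon = int(math.ceil((cfg.lon_max - cfg.lon_min) / cell - 1e-9))
    nlat = int(math.ceil((cfg.lat_max - cfg.lat_min) / cell - 1e-9))
    lons = cfg.lon_min + cell / 2 + cell * np.arange(-pad_cells, nlon + pad_cells)
    lats = cfg.lat_min + cell / 2 + cell * np.arange(-pad_cells, nlat + pad_cells)
    return lons, lats


def _field(cfg, cell, pad, values, name, units, time=None) -> GriddedField:
    lons, lats = _grid(cfg, cell, pad)
    return GriddedField(
        name=name,
        units=units,
        origin_lon=float(lons[0]),
        origin_lat=float(lats[0]),
        dlon=cell,
        dlat=cell,
        values=values,
        time=time,
    )


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def _rank_map(z: np.ndarray, ppf) -> np.ndarray:
    """Impose an exact marginal on a smooth field via its spatial ranks."""
    flat = z.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    u = (ranks + 0.5) / flat.size
    return ppf(u).reshape(z.shape)


# ---------------------------------------------------------------------------
# truth surfaces


def make_coefficient_surfaces(cfg: SceneConfig, seed: int) -> SceneTruth:
    """Six smooth coefficient surfaces: stated mean + sinusoid perturbation."""
    lons, lats = _grid(cfg, cfg.beta_cell_deg, pad_cells=3)
    lon2, lat2 = np.meshgrid(lons, lats)
    surfaces, components = {}, {}
    for i, name in enumerate(COEF_NAMES):
        rng = _rng(seed, 10, i)
        comps = _sample_components(
            rng, cfg.coef_amps[i], cfg.coef_corr_len_deg, cfg.n_harmonics
        )
        pert = _eval_components(comps, lon2, lat2)
        # wavelengths can exceed the domain, so the realised in-domain RMS
        # depends on the phase draw; rescale so the perturbation has exactly
        # the stated amplitude (components scaled identically, keeping the
        # closed-form smoothness bound valid)
        if comps and pert.std() > 0:
            c = cfg.coef_amps[i] / pert.std()
            pert *= c
            comps = [
                HarmonicComponent(h.amp * c, h.kx, h.ky, h.phase) for h in comps
            ]
        vals = cfg.coef_means[i] + pert
        surfaces[name] = GriddedField(
            name=name,
            units="",
            origin_lon=float(lons[0]),
            origin_lat=float(lats[0]),
            dlon=cfg.beta_cell_deg,
            dlat=cfg.beta_cell_deg,
            values=vals,
        )
        components[name] = comps
    return SceneTruth(surfaces=surfaces, components=components, noise_sd=cfg.noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# stations


def make_station_network(cfg: SceneConfig, seed: int) -> list[tuple[str, float, float]]:
    """Station network with tunable clustering (0 = spatially uniform).

    A ``clustering`` fraction of stations is drawn from Gaussian blobs
    around random cluster centers (dense-urban coverage); the rest are
    uniform (sparse rural/western coverage).
    """
    rng = _rng(seed, 20)
    n_clustered = int(round(cfg.clustering * cfg.n_stations))
    pts = []
    if n_clustered:
        centers = np.column_stack(
            [
                rng.uniform(cfg.lon_min + 0.5, cfg.lon_max - 0.5, cfg.n_clusters),
                rng.uniform(cfg.lat_min + 0.5, cfg.lat_max - 0.5, cfg.n_clusters),
            ]
        )
        which = rng.integers(0, cfg.n_clusters, n_clustered)
        for c in which:
            while True:  # truncate to the domain by resampling
                p = centers[c] + rng.normal(0, cfg.cluster_sd_deg, 2)
                if cfg.lon_min < p[0] < cfg.lon_max and cfg.lat_min < p[1] < cfg.lat_max:
                    pts.append(p)
                    break
    n_uniform = cfg.n_stations - n_clustered
    if n_uniform:
        u = np.column_stack(
            [
                rng.uniform(cfg.lon_min, cfg.lon_max, n_uniform),
                rng.uniform(cfg.lat_min, cfg.lat_max, n_uniform),
            ]
        )
        pts.extend(u)
    return [(f"S{i:04d}", float(p[0]), float(p[1])) for i, p in enumerate(pts)]


# ---------------------------------------------------------------------------
# meteorology


def _season_index(day: _dt.date) -> int:
    return {12: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 2, 7: 2, 8: 2}.get(day.month, 3)


def _smooth_z(cfg: SceneConfig, seed: int, stream, lon2, lat2, corr_len) -> np.ndarray:
    rng = _rng(seed, *stream)
    comps = _sample_components(rng, 1.0, corr_len, cfg.n_harmonics)
    return _eval_components(comps, lon2, lat2)


def make_meteorology(
    cfg: SceneConfig, day: _dt.date, seed: int, day_index: int | None = None
) -> dict[str, GriddedField]:
    """Per-day meteorological fields {pblh, rh, st, ps, u, v} on the met grid.

    Fields are spatially smooth; marginal shapes are imposed by quantile
    rank-mapping: PBLH log-normal (km), RH and temperature Weibull, winds
    Gaussian.  Pressure derives from a day-invariant plateau/lowland
    elevation surface through the barometric formula, which makes its
    marginal bimodal when ``bimodal_pressure`` is set.
    """
    di = day_index if day_index is not None else day.toordinal()
    lons, lats = _grid(cfg, cfg.met_cell_deg, pad_cells=2)
    lon2, lat2 = np.meshgrid(lons, lats)
    L = cfg.met_corr_len_deg

    def fld(values, name, units):
        return _field(cfg, cfg.met_cell_deg, 2, values, name, units, time=day.isoformat())

    out = {}
    # PBLH: log-normal, strictly positive
    z = _smooth_z(cfg, seed, (30, di, 0), lon2, lat2, L)
    if cfg.pblh_sigma == 0:
        pblh = np.full_like(z, math.exp(cfg.pblh_mu))
    else:
        pblh = _rank_map(
            z, lambda u: stats.lognorm.ppf(u, cfg.pblh_sigma, scale=math.exp(cfg.pblh_mu))
        )
    out["pblh"] = fld(pblh, "pblh", "km")

    # RH: Weibull, clipped into [0, rh_cap] (config validation keeps the
    # 0.9999 quantile below 100, so the clip is a no-op in practice)
    z = _smooth_z(cfg, seed, (30, di, 1), lon2, lat2, L)
    rh = _rank_map(
        z, lambda u: stats.weibull_min.ppf(u, cfg.rh_weibull_shape, scale=cfg.rh_weibull_scale)
    )
    out["rh"] = fld(np.clip(rh, 0.0, cfg.rh_cap), "rh", "%")

    # surface temperature: base + Weibull excursion + seasonal offset
    z = _smooth_z(cfg, seed, (30, di, 2), lon2, lat2, L)
    st = cfg.st_base + _rank_map(
        z, lambda u: stats.weibull_min.ppf(u, cfg.st_weibull_shape, scale=cfg.st_weibull_scale)
    )
    out["st"] = fld(st + cfg.st_season_offset[_season_index(day)], "st", "K")

    # pressure via a fixed elevation surface (bimodal when plateau present);
    # standardise the realised field so the sigmoid saturates into distinct
    # lowland (~0.3 km) and plateau (~4 km) branches
    z_elev = _smooth_z(cfg, seed, (31,), lon2, lat2, 2 * L)  # terrain: day-invariant
    z_std = z_elev / max(z_elev.std(), 1e-12)
    if cfg.bimodal_pressure:
        elev_km = 0.3 + 3.7 / (1.0 + np.exp(-5.0 * z_std))
    else:
        elev_km = np.clip(0.5 + 0.3 * z_elev, 0.05, None)
    z = _smooth_z(cfg, seed, (30, di, 3), lon2, lat2, L)
    ps = 101325.0 * np.exp(-elev_km / 8.4) * np.exp(0.004 * z)
    out["ps"] = fld(ps, "ps", "Pa")

    # winds: Gaussian components; speed = hypot(u, v) is then Weibull-like
    zu = _smooth_z(cfg, seed, (30, di, 4), lon2, lat2, L)
    zv = _smooth_z(cfg, seed, (30, di, 5), lon2, lat2, L)
    out["u"] = fld(cfg.wind_mean[0] + cfg.wind_sd * zu, "u", "m/s")
    out["v"] = fld(cfg.wind_mean[1] + cfg.wind_sd * zv, "v", "m/s")
    return out


def make_precip(cfg: SceneConfig, day: _dt.date, seed: int) -> GriddedField:
    """Daily total precipitation (mm): mostly-zero thresholded smooth field."""
    di = day.toordinal()
    lons, lats = _grid(cfg, cfg.met_cell_deg, pad_cells=2)
    lon2, lat2 = np.meshgrid(lons, lats)
    z = _smooth_z(cfg, seed, (32, di), lon2, lat2, cfg.met_corr_len_deg)
    precip = np.maximum(0.0, z - cfg.precip_threshold) * cfg.precip_scale_mm
    return _field(cfg, cfg.met_cell_deg, 2, precip, "precip", "mm", time=day.isoformat())


# ---------------------------------------------------------------------------
# AOD granules


def _bilinear_grid(field: GriddedField, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Vectorised bilinear sample of an unmasked field at a lon x lat grid."""
    x = (lons - field.origin_lon) / field.dlon
    y = (lats - field.origin_lat) / field.dlat
    j0 = np.clip(np.floor(x).astype(int), 0, field.shape[1] - 2)
    i0 = np.clip(np.floor(y).astype(int), 0, field.shape[0] - 2)
    fx, fy = x - j0, y - i0
    v = field.values
    fx2, fy2 = np.meshgrid(fx, fy)
    j2, i2 = np.meshgrid(j0, i0)
    bot = v[i2, j2] * (1 - fx2) + v[i2, j2 + 1] * fx2
    top = v[i2 + 1, j2] * (1 - fx2) + v[i2 + 1, j2 + 1] * fx2
    return bot * (1 - fy2) + top * fy2


def make_column_aod(
    cfg: SceneConfig, pblh: GriddedField, day: _dt.date, seed: int
) -> GriddedField:
    """Noiseless fine-grid column AOD = revised-AOD surface x PBLH.

    The revised-AOD (per-km) surface is a smooth log-normal field; the
    column value multiplies back by the boundary-layer height sampled
    bilinearly at each fine cell center, so dividing a retrieved pixel by
    PBLH recovers the revised value the generator used.
    """
    di = day.toordinal()
    lons, lats = _grid(cfg, cfg.fine_cell_deg, pad_cells=0)
    lon2, lat2 = np.meshgrid(lons, lats)
    z = _smooth_z(cfg, seed, (40, di), lon2, lat2, cfg.aod_corr_len_deg)
    raod = _rank_map(z, lambda u: stats.lognorm.ppf(u, cfg.raod_sigma, scale=cfg.raod_scale))
    column = raod * _bilinear_grid(pblh, lons, lats)
    return _field(cfg, cfg.fine_cell_deg, 0, column, "aod_column", "1", time=day.isoformat())


def make_aod_granules(
    column: GriddedField, cfg: SceneConfig, day: _dt.date, seed: int
) -> tuple[AODGranule, AODGranule]:
    """DT (fine) and DB (coarse) granules from the noiseless column field.

    DT: column + retrieval noise, missing over an iid bright-surface mask,
    QA drawn from the configured probabilities.  DB: block average of the
    fine field onto the coarse grid (covering bright cells) + noise.
    """
    di = day.toordinal()
    rng = _rng(seed, 41, di)
    fine_vals = column.values + rng.normal(0, cfg.dt_noise_sd, column.shape)
    bright = rng.random(column.shape) < cfg.bright_fraction
    dt_qa = rng.choice(4, size=column.shape, p=cfg.dt_qa_probs).astype(np.int8)
    dt = AODGranule(
        field=GriddedField(
            name="aod_dt",
            units="1",
            origin_lon=column.origin_lon,
            origin_lat=column.origin_lat,
            dlon=column.dlon,
            dlat=column.dlat,
            values=np.where(bright, 0.0, np.maximum(fine_vals, 0.0)),
            mask=bright,
            time=column.time,
        ),
        qa=dt_qa,
        algorithm="DT",
        resolution_km=3.0,
    )

    clons, clats = _grid(cfg, cfg.coarse_cell_deg, pad_cells=0)
    coarse_spec = GriddedField(
        name="aod_db",
        units="1",
        origin_lon=float(clons[0]),
        origin_lat=float(clats[0]),
        dlon=cfg.coarse_cell_deg,
        dlat=cfg.coarse_cell_deg,
        values=np.zeros((len(clats), len(clons))),
        time=column.time,
    )
    flon2, flat2 = np.meshgrid(column.lons(), column.lats())
    ci, cj = coarse_spec.cell_index(flon2, flat2)
    inside = ci >= 0
    sums = np.zeros(coarse_spec.shape)
    counts = np.zeros(coarse_spec.shape)
    np.add.at(sums, (ci[inside], cj[inside]), column.values[inside])
    np.add.at(counts, (ci[inside], cj[inside]), 1.0)
    db_mask = counts == 0
    with np.errstate(invalid="ignore"):
        db_vals = np.where(db_mask, 0.0, sums / np.maximum(counts, 1.0))
    db_vals = np.where(db_mask, 0.0, db_vals + rng.normal(0, cfg.db_noise_sd, db_vals.shape))
    db_qa = rng.choice(4, size=coarse_spec.shape, p=cfg.db_qa_probs).astype(np.int8)
    db = AODGranule(
        field=coarse_spec.copy_with(values=np.maximum(db_vals, 0.0), mask=db_mask),
        qa=db_qa,
        algorithm="DB",
        resolution_km=10.0,
    )
    return dt, db


def fuse_scene_granules(dt: AODGranule, db: AODGranule) -> GriddedField:
    """QA-filter both granules and fuse onto the fine grid (DT precedence)."""
    dt_f = apply_qa_filter(dt)
    db_f = apply_qa_filter(db)
    db_fine = regrid_db_to_fine(db_f.field, dt_f.field)
    return fuse_dt_db(dt_f.field, db_fine)


# ---------------------------------------------------------------------------
# observations


def make_observations(
    truth: SceneTruth,
    met: Mapping[str, GriddedField],
    precip_by_date: Mapping[_dt.date, GriddedField],
    stations: Sequence[tuple[str, float, float]],
    column: GriddedField,
    cfg: SceneConfig,
    day: _dt.date,
    seed: int,
) -> tuple[list[StationRecord], list[ModelRow]]:
    """Hourly PM2.5 records (13:00/14:00 local) and noiseless truth rows.

    Regressors are computed with the pipeline's own access rules: revised
    AOD from the noiseless column pixel divided by bilinear PBLH, the
    remaining regressors bilinear, wind speed = hypot(u, v).  The revised
    response is the linear predictor with the truth coefficients; recorded
    dry PM2.5 adds Gaussian noise on the revised scale and per-hour jitter
    on the dry scale.
    """
    rng = _rng(seed, 50, day.toordinal())
    records: list[StationRecord] = []
    truth_rows: list[ModelRow] = []
    for sid, lon, lat in stations:
        vals = {}
        for name in ("pblh", "rh", "st", "ps", "u", "v"):
            v = bilinear_at(met[name], lon, lat)
            if v is None:
                raise ValidationError(f"station {sid} outside {name} field domain")
            vals[name] = v
        i, j = column.cell_index(lon, lat)
        if int(i) < 0:
            raise ValidationError(f"station {sid} outside the AOD domain")
        raod = float(column.values[int(i), int(j)]) / vals["pblh"]
        offset = zone_offset(lon)
        lp = prev_day_precip(precip_by_date, lon, lat, day, offset)
        if lp is None:
            raise ValidationError(f"no previous-day precipitation for {sid} on {day}")
        ws = float(np.hypot(vals["u"], vals["v"]))
        x = np.array([1.0, raod, lp, vals["st"], vals["ps"], ws])
        beta = truth.beta_at(lon, lat)
        revised_true = float(x @ beta)
        dry_true = dry_pm25(max(revised_true, 0.0), vals["rh"])
        truth_rows.append(
            ModelRow(
                station_id=sid,
                lon=lon,
                lat=lat,
                day=day,
                revised_aod=raod,
                last_prec=lp,
                st=vals["st"],
                ps=vals["ps"],
                ws=ws,
                rh=vals["rh"],
                pblh=vals["pblh"],
                revised_pm25=max(revised_true, 0.0),
                pm25=dry_true,
            )
        )
        noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
        dry_daily = dry_pm25(max(revised_true + noise, 0.0), vals["rh"])
        h1, h2 = overpass_hours_beijing(offset)
        for hour in (h1, h2):
            jitter = rng.normal(0.0, cfg.hour_jitter_sd) if cfg.hour_jitter_sd > 0 else 0.0
            records.append(
                StationRecord(
                    station_id=sid,
                    lon=lon,
                    lat=lat,
                    date=day,
                    hour_beijing=hour,
                    pm25=max(dry_daily + jitter, 0.0),
                )
            )
    return records, truth_rows


# ---------------------------------------------------------------------------
# full scene


def generate_scene(
    cfg: SceneConfig | None = None,
    seed: int = 0,
    dates: Sequence[_dt.date] | None = None,
) -> Scene:
    """Generate a complete reproducible scene from (config, seed)."""
    cfg = cfg or SceneConfig()
    dates = list(dates) if dates is not None else default_dates()
    truth = make_coefficient_surfaces(cfg, seed)
    stations = make_station_network(cfg, seed)

    met, precip, granules, fused, column_aod = {}, {}, {}, {}, {}
    prev_dates = sorted({d - _dt.timedelta(days=1) for d in dates} | set(dates))
    for d in prev_dates:
        precip[d] = make_precip(cfg, d, seed)

    records: list[StationRecord] = []
    truth_rows: dict = {}
    for idx, d in enumerate(dates):
        met[d] = make_meteorology(cfg, d, seed, day_index=idx)
        column = make_column_aod(cfg, met[d]["pblh"], d, seed)
        column_aod[d] = column
        dt, db = make_aod_granules(column, cfg, d, seed)
        granules[d] = (dt, db)
        fused[d] = fuse_scene_granules(dt, db)
        recs, rows = make_observations(
            truth, met[d], precip, stations, column, cfg, d, seed
        )
        records.extend(recs)
        truth_rows[d] = rows
    return Scene(
        config=cfg,
        seed=seed,
        truth=truth,
        stations=stations,
        dates=dates,
        met=met,
        precip=precip,
        granules=granules,
        fused=fused,
        column_aod=column_aod,
        records=records,
        truth_rows=truth_rows,
    )
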