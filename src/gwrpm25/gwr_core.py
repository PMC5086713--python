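"""Geographically weighted regression with adaptive bandwidth, from scratch.

The model is a locally linear regression of humidity-revised PM2.5 on five
regressors (PBLH-revised AOD, previous-day precipitation, surface
temperature, surface pressure, wind speed) plus an intercept, refitted at
every calibration location with distance-decay weights.  One fit per day:
the coefficients are indexed by both location and day.

Distances are great-circle km (the national domain spans tens of degrees of
latitude, so Euclidean degrees would distort the kernel).  The default
kernel is the compactly supported adaptive bisquare, whose bandwidth at a
location is the distance to its k-th nearest calibration point; k is chosen
by minimising the leave-one-out cross-validation residual sum of squares,
searched by golden section on the integers with an exhaustive sweep of the
final bracket (tie-break: smallest k, favouring locality).

The weighted least-squares solve scales regressor columns to unit RMS and
uses a QR-based solver, so the wildly different natural scales of the
regressors (pressure in Pa against AOD near unity) do not degrade the
solution; the returned coefficients are on the original scales.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ModelRow, RunConfig

__all__ = [
    "EARTH_RADIUS_KM",
    "REGRESSOR_NAMES",
    "SingularFitError",
    "GWRFit",
    "haversine_km",
    "pairwise_km",
    "bisquare_weight",
    "gaussian_weight",
    "kernel_weights",
    "adaptive_bandwidth_km",
    "design_matrix",
    "local_wls",
    "select_bandwidth",
    "fit_gwr",
    "predict_gwr",
    "predict_at",
]

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
N_REGRESSORS = 6
REGRESSOR_NAMES = ("intercept", "revised_aod", "last_prec", "st", "ps", "ws")


class SingularFitError(np.linalg.LinAlgError):
    """A local weighted design matrix is rank deficient."""


@dataclass
class GWRFit:
    """Per-location GWR calibration result for one day."""

    lonlat: np.ndarray  # (n, 2)
    betas: np.ndarray  # (n, 6) on original regressor scales
    local_r2: np.ndarray  # (n,)
    k: int
    kernel: str
    day: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.betas.shape[1] != N_REGRESSORS:
            raise ValueError("coefficient vectors must have length 6")
        if np.any(self.local_r2 > 1 + 1e-12):
            raise ValueError("local R2 cannot exceed 1")
        if self.k < N_REGRESSORS + 1:
            raise ValueError("k must be at least regressors + 1")


# ---------------------------------------------------------------------------
# Distances and kernels


def haversine_km(p1, p2) -> float | np.ndarray:
    """Great-circle distance between (lon, lat) points, km."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    lon1, lat1 = np.radians(p1[..., 0]), np.radians(p1[..., 1])
    lon2, lat2 = np.radians(p2[..., 0]), np.radians(p2[..., 1])
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


def pairwise_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(m, n) great-circle distance matrix between (lon, lat) arrays."""
    return haversine_km(np.asarray(a, float)[:, None, :], np.asarray(b, float)[None, :, :])


def bisquare_weight(d_km, bandwidth_km):
    """Bisquare kernel (1 - (d/b)^2)^2 for d < b, else 0 (compact support)."""
    if np.any(np.asarray(bandwidth_km) <= 0):
        raise ValueError("bandwidth must be positive")
    u = np.asarray(d_km, float) / bandwidth_km
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return float(w) if w.ndim == 0 else w


def gaussian_weight(d_km, bandwidth_km):
    """Gaussian kernel exp(-(d/b)^2 / 2); strictly positive everywhere."""
    if np.any(np.asarray(bandwidth_km) <= 0):
        raise ValueError("bandwidth must be positive")
    u = np.asarray(d_km, float) / bandwidth_km
    w = np.exp(-0.5 * u**2)
    return float(w) if w.ndim == 0 else w


def kernel_weights(d_km, bandwidth_km, kernel: str):
    if kernel == "bisquare":
        return bisquare_weight(d_km, bandwidth_km)
    if kernel == "gaussian":
        return gaussian_weight(d_km, bandwidth_km)
    if kernel == "uniform":
        w = np.where(np.asarray(d_km, float) < bandwidth_km, 1.0, 0.0)
        return float(w) if w.ndim == 0 else w
    raise ValueError(f"unknown kernel {kernel!r}")


def adaptive_bandwidth_km(distances, k: int, min_k: int = 1) -> float:
    """Distance to the k-th nearest calibration point.

    Under a compactly supported kernel, points tied exactly at this distance
    receive weight zero.  Fitting callers pass ``min_k = N_REGRESSORS + 2``
    so an under-determined local fit is rejected up front; the bare helper
    accepts any positive k.
    """
    d = np.asarray(distances, dtype=float)
    if k < max(min_k, 1):
        raise ValueError(f"k={k} below the floor {min_k} (under-determined local fit)")
    if k > d.size:
        raise ValueError(f"k={k} exceeds {d.size} calibration points")
    return float(np.partition(d, k - 1)[k - 1])


# ---------------------------------------------------------------------------
# Weighted least squares


def design_matrix(rows: Sequence[ModelRow]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, lonlat) arrays for a row list; X columns follow REGRESSOR_NAMES."""
    X = np.array(
        [[1.0, r.revised_aod, r.last_prec, r.st, r.ps, r.ws] for r in rows]
    )
    y = np.array([r.revised_pm25 for r in rows])
    lonlat = np.array([[r.lon, r.lat] for r in rows])
    return X, y, lonlat


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve argmin sum w_i (y_i - x_i b)^2; return (beta, weighted R2).

    A regressor that is identically zero over the positive-weight rows
    (previous-day precipitation in a locally dry neighbourhood is the
    canonical case) contributes nothing to the fit; its coefficient is
    pinned to zero and the reduced system solved.  Any remaining rank
    deficiency (duplicated or collinear columns) raises.
    """
    pos = w > 0
    if pos.sum() < N_REGRESSORS + 1:
        raise SingularFitError(
            f"only {int(pos.sum())} observations with positive weight"
        )
    sw = np.sqrt(w[pos])
    Xp = X[pos]
    live = np.abs(Xp).max(axis=0) > 0
    # unit-RMS column scaling keeps QR well conditioned across Pa vs AOD scales
    scale = np.sqrt(np.mean((Xp[:, live] * sw[:, None]) ** 2, axis=0))
    scale[scale == 0] = 1.0
    Xs = (Xp[:, live] / scale) * sw[:, None]
    beta_s, _, rank, _ = np.linalg.lstsq(Xs, y[pos] * sw, rcond=None)
    if rank < int(live.sum()):
        raise SingularFitError("weighted design matrix is rank deficient")
    beta = np.zeros(X.shape[1])
    beta[live] = beta_s / scale
    resid = y[pos] - X[pos] @ beta
    ybar = np.average(y[pos], weights=w[pos])
    tss = np.sum(w[pos] * (y[pos] - ybar) ** 2)
    rss = np.sum(w[pos] * resid**2)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return beta, float(r2)


def local_wls(
    rows: Sequence[ModelRow],
    target_lonlat,
    bandwidth_km: float,
    kernel: str = "bisquare",
) -> tuple[np.ndarray, float]:
    """Weighted least squares calibrated at one target location.

    Raises :class:`SingularFitError` naming the location if the weighted
    design matrix is rank deficient or too few observations carry weight.
    """
    X, y, lonlat = design_matrix(rows)
    d = haversine_km(lonlat, np.asarray(target_lonlat, float))
    w = kernel_weights(d, bandwidth_km, kernel)
    try:
        return _wls(X, y, np.atleast_1d(w))
    except SingularFitError as exc:
        raise SingularFitError(f"singular local fit at {tuple(target_lonlat)}: {exc}")


# ---------------------------------------------------------------------------
# Bandwidth selection


def _loo_score(X, y, D, k: int, kernel: str) -> float:
    """Leave-one-out CV residual sum of squares for neighbour count k."""
    n = len(y)
    Dx = D.copy()
    np.fill_diagonal(Dx, np.inf)
    # k-th nearest among the *other* points, mirroring the LOO fit
    b = np.partition(Dx, k - 1, axis=1)[:, k - 1]
    sse, used = 0.0, 0
    for i in range(n):
        w = kernel_weights(Dx[i], b[i], kernel)  # self weight 0 (d = inf)
        try:
            beta, _ = _wls(X, y, w)
        except SingularFitError:
            continue
        sse += (y[i] - X[i] @ beta) ** 2
        used += 1
    if used == 0:
        return math.inf
    return sse * n / used  # renormalise if some locations were singular


def select_bandwidth(
    rows: Sequence[ModelRow],
    kernel: str = "bisquare",
    k_range: tuple[int, int] | Sequence[int] = (20, 120),
    exhaustive: bool = False,
) -> int:
    """Adaptive neighbour count k* minimising the LOO CV score.

    Golden-section search on the integers, falling back to an exhaustive
    sweep once the bracket is narrower than 10 (and over the whole range
    when ``exhaustive=True``); ties resolve to the smallest k.
    """
    X, y, lonlat = design_matrix(rows)
    n = len(y)
    if isinstance(k_range, tuple) and len(k_range) == 2:
        lo, hi = k_range
    else:
        ks = sorted(int(k) for k in k_range)
        lo, hi = ks[0], ks[-1]
    lo = max(lo, N_REGRESSORS + 2)
    hi = min(hi, n - 1)  # LOO leaves n-1 candidate neighbours
    if lo > hi:
        raise ValueError(f"empty bandwidth range after clipping: [{lo}, {hi}]")
    D = pairwise_km(lonlat, lonlat)
    cache: dict[int, float] = {}

    def f(k: int) -> float:
        if k not in cache:
            cache[k] = _loo_score(X, y, D, k, kernel)
        return cache[k]

    if not exhaustive:
        g = (math.sqrt(5.0) - 1.0) / 2.0
        while hi - lo > 10:
            span = hi - lo
            x1 = hi - int(round(g * span))
            x2 = lo + int(round(g * span))
            if x1 >= x2:
                break
            if f(x1) <= f(x2):
                hi = x2
            else:
                lo = x1
    scores = {k: f(k) for k in range(lo, hi + 1)}
    if all(math.isinf(s) for s in scores.values()):
        raise SingularFitError("all candidate bandwidths give singular fits")
    best = min(scores.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return int(best)


# ---------------------------------------------------------------------------
# Fitting and prediction


def fit_gwr(rows: Sequence[ModelRow], config: RunConfig, k: int | None = None) -> GWRFit:
    """Calibrate the GWR at every row location for one day.

    ``k`` overrides bandwidth selection (used when a day's neighbour count
    has already been chosen); otherwise the adaptive k* is searched.
    """
    if len(rows) < config.min_rows:
        raise ValueError(f"{len(rows)} rows below the configured floor {config.min_rows}")
    day = rows[0].day
    if k is None:
        k = select_bandwidth(rows, config.kernel, (config.k_min, config.k_max))
    X, y, lonlat = design_matrix(rows)
    D = pairwise_km(lonlat, lonlat)
    kk = min(k, len(rows))
    b = np.partition(D, kk - 1, axis=1)[:, kk - 1]
    betas = np.empty((len(rows), N_REGRESSORS))
    r2 = np.empty(len(rows))
    singular: list[tuple[float, float]] = []
    for i in range(len(rows)):
        w = kernel_weights(D[i], b[i], config.kernel)
        try:
            betas[i], r2[i] = _wls(X, y, w)
        except SingularFitError:
            singular.append((rows[i].lon, rows[i].lat))
    if singular:
        raise SingularFitError(f"singular local fits at {singular}")
    return GWRFit(lonlat=lonlat, betas=betas, local_r2=r2, k=kk, kernel=config.kernel, day=day)


def predict_at(
    rows: Sequence[ModelRow],
    config: RunConfig,
    target_lonlat: np.ndarray,
    target_X: np.ndarray,
    k: int | None = None,
) -> np.ndarray:
    """Predict revised PM2.5 at arbitrary points given their regressors.

    Each target gets its own local calibration from the station rows
    (adaptive bandwidth = distance to the k-th nearest calibration point
    from the *target*).  Singular local fits yield NaN by default, or the
    global OLS prediction when ``config.singular_fallback == "global"``.
    """
    X, y, lonlat = design_matrix(rows)
    target_lonlat = np.atleast_2d(np.asarray(target_lonlat, float))
    target_X = np.atleast_2d(np.asarray(target_X, float))
    if k is None:
        k = select_bandwidth(rows, config.kernel, (config.k_min, config.k_max))
    kk = min(k, len(rows))
    D = pairwise_km(target_lonlat, lonlat)
    b = np.partition(D, kk - 1, axis=1)[:, kk - 1]
    b = np.maximum(b, 1e-9)
    out = np.full(len(target_lonlat), np.nan)
    global_beta = None
    for i in range(len(target_lonlat)):
        w = kernel_weights(D[i], b[i], config.kernel)
        try:
            beta, _ = _wls(X, y, w)
        except SingularFitError:
            if config.singular_fallback == "global":
                if global_beta is None:
                    global_beta, _ = _wls(X, y, np.ones(len(y)))
                beta = global_beta
            else:
                log.info("singular prediction fit at %s; missing", target_lonlat[i])
                continue
        out[i] = target_X[i] @ beta
    return out


def predict_gwr(
    rows: Sequence[ModelRow],
    config: RunConfig,
    targets: Sequence[ModelRow],
    k: int | None = None,
) -> np.ndarray:
    """Predict revised PM2.5 at target rows' locations from calibration rows."""
    tX, _, tll = design_matrix(targets)
    return predict_at(rows, config, tll, tX, k=k)
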