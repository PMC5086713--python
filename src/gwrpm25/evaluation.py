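"""Seasonal 10-fold cross-validation and model diagnostics.

Rows are pooled by meteorological season (MAM spring, JJA summer, SON
autumn, DJF winter) and partitioned into k random folds at the record
level.  Each fold is held out once: the per-day GWR is recalibrated on the
other nine folds, held-out rows are predicted at their own locations, and
predictions are back-transformed to the measured (dry) scale before
computing metrics — validation compares what stations actually report.

R² is the squared Pearson correlation of held-out estimated vs measured
(the convention matching a scatter-plot regression line); a
sum-of-squares R² is carried as a secondary column since the two differ
when the fit line departs from the 1:1 line.  The slope/intercept of the
OLS line ``estimated = a * measured + b`` diagnose attenuation: noise in
the response pulls the slope below 1 and the intercept above 0, i.e. the
model overestimates low and underestimates high concentrations.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ModelRow, RunConfig
from .gwr_core import SingularFitError, predict_gwr, select_bandwidth
from .physical_corrections import dry_pm25

__all__ = [
    "SEASONS",
    "season_of",
    "make_folds",
    "Metrics",
    "metrics",
    "CVReport",
    "crossval",
]

log = logging.getLogger(__name__)

SEASONS = ("spring", "summer", "autumn", "winter")

_MONTH_SEASON = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def season_of(date: _dt.date) -> str:
    """Meteorological season: MAM / JJA / SON / DJF."""
    return _MONTH_SEASON[date.month]


def make_folds(count: int, k: int, seed: int) -> np.ndarray:
    """Random fold label (0..k-1) per row; sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if count < k:
        raise ValueError(f"cannot split {count} rows into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.arange(count) % k
    return rng.permutation(labels)


@dataclass(frozen=True)
class Metrics:
    """Agreement statistics between measured and estimated values."""

    n: int
    r2: float  # squared Pearson correlation
    rmse: float
    mae: float
    slope: float  # OLS estimated = slope * measured + intercept
    intercept: float
    r2_ss: float  # 1 - RSS/TSS about the 1:1 line (secondary)


def metrics(measured, estimated) -> Metrics:
    """R², RMSE, MAE and the fitted line of estimated on measured."""
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ValueError("measured and estimated must have equal length")
    if m.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(m) == 0:
        raise ValueError("measured values have zero variance")
    resid = e - m
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    r = float(np.corrcoef(m, e)[0, 1])
    slope, intercept = np.polyfit(m, e, 1)
    tss = float(np.sum((m - m.mean()) ** 2))
    r2_ss = 1.0 - float(np.sum(resid**2)) / tss
    return Metrics(
        n=int(m.size),
        r2=r * r,
        rmse=rmse,
        mae=mae,
        slope=float(slope),
        intercept=float(intercept),
        r2_ss=r2_ss,
    )


@dataclass
class CVReport:
    """Per-season cross-validation results plus bookkeeping."""

    seasons: dict  # season -> Metrics
    fold_seed: int
    k_folds: int
    skipped: Counter = field(default_factory=Counter)
    bandwidths: dict = field(default_factory=dict)  # day -> k*

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in SEASONS:
            if s not in self.seasons:
                continue
            met = self.seasons[s]
            rows.append(
                {
                    "season": s,
                    "n": met.n,
                    "r2": met.r2,
                    "rmse": met.rmse,
                    "mae": met.mae,
                    "slope": met.slope,
                    "intercept": met.intercept,
                    "r2_ss": met.r2_ss,
                }
            )
        return pd.DataFrame(rows)


def crossval(
    rows: Sequence[ModelRow],
    config: RunConfig,
    k: int | None = None,
    seed: int | None = None,
) -> CVReport:
    """Seasonal k-fold cross-validation of the per-day GWR.

    For each fold, every day's model is refitted on that day's rows from
    the other folds and evaluated on the held-out rows of the same day;
    pairs are pooled within each season.  Days whose training set falls
    below a fittable size after masking a fold are skipped and counted.
    """
    k = k if k is not None else config.folds
    seed = seed if seed is not None else config.seed
    by_season: dict[str, list[ModelRow]] = defaultdict(list)
    for r in rows:
        by_season[season_of(r.day)].append(r)

    # adaptive bandwidth chosen once per day (see methods note); the
    # "per-fold" policy reselects on each training subset instead
    day_k: dict[_dt.date, int] = {}
    if config.cv_bandwidth_policy == "per-day":
        by_day: dict[_dt.date, list[ModelRow]] = defaultdict(list)
        for r in rows:
            by_day[r.day].append(r)
        for d, drows in by_day.items():
            day_k[d] = select_bandwidth(
                drows, config.kernel, (config.k_min, min(config.k_max, len(drows) - 1))
            )

    report = CVReport(seasons={}, fold_seed=seed, k_folds=k)
    report.bandwidths = dict(day_k)
    for si, season in enumerate(SEASONS):
        srows = by_season.get(season)
        if not srows:
            continue
        labels = make_folds(len(srows), k, int(np.random.SeedSequence([seed, si]).generate_state(1)[0] % 2**31))
        measured, estimated = [], []
        for fold in range(k):
            test_idx = np.flatnonzero(labels == fold)
            train_by_day: dict[_dt.date, list[ModelRow]] = defaultdict(list)
            test_by_day: dict[_dt.date, list[ModelRow]] = defaultdict(list)
            for i, r in enumerate(srows):
                (test_by_day if labels[i] == fold else train_by_day)[r.day].append(r)
            for d, test_rows in test_by_day.items():
                train = train_by_day.get(d, [])
                if len(train) < config.k_min + 1:
                    report.skipped[f"{season}:unfittable_day"] += len(test_rows)
                    continue
                if config.cv_bandwidth_policy == "per-day":
                    kd = min(day_k[d], len(train) - 1)
                else:
                    kd = select_bandwidth(
                        train, config.kernel, (config.k_min, min(config.k_max, len(train) - 1))
                    )
                try:
                    pred_rev = predict_gwr(train, config, test_rows, k=kd)
                except SingularFitError:
                    report.skipped[f"{season}:singular_day"] += len(test_rows)
                    continue
                for r, pr in zip(test_rows, pred_rev):
                    if not np.isfinite(pr):
                        report.skipped[f"{season}:singular_point"] += 1
                        continue
                    measured.append(r.pm25)
                    estimated.append(dry_pm25(max(pr, 0.0), r.rh))
        if len(measured) >= 3:
            report.seasons[season] = metrics(measured, estimated)
        else:
            report.skipped[f"{season}:too_few_pairs"] += len(measured)
    if report.skipped:
        log.info("cross-validation skipped rows: %s", dict(report.skipped))
    return report
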