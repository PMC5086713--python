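"""Seasonal aggregation of predicted surfaces, WHO-target exceedance and
descriptive statistics.

Seasonal surfaces are per-cell means of the daily predicted fields, with a
minimum-valid-days mask (bright surfaces and QA failures leave gaps, and a
cell estimated on only a couple of days would misrepresent the season).
Exceedance is reported against the WHO interim targets IT-1 (35 μg/m³) and
IT-3 (15 μg/m³) as a percentage above the standard.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import GriddedField, ModelRow, RunConfig
from .gwr_core import predict_at, select_bandwidth
from .integration import bilinear_at, pixel_at, prev_day_precip, zone_offset
from .physical_corrections import revise_aod

__all__ = [
    "WHO_IT1",
    "WHO_IT3",
    "seasonal_mean",
    "who_exceedance_pct",
    "DescriptiveStats",
    "descriptive_stats",
    "predict_surface",
    "region_summary",
]

WHO_IT1 = 35.0  # μg/m³, WHO interim target 1
WHO_IT3 = 15.0  # μg/m³, WHO interim target 3


def seasonal_mean(fields: Sequence[GriddedField], min_valid_days: int = 5) -> GriddedField:
    """Per-cell mean over days where the cell is valid.

    Cells observed on fewer than ``min_valid_days`` days come back masked.
    Day order is irrelevant (a permuted stack gives the same field).
    """
    if not fields:
        raise ValueError("empty field stack")
    ref = fields[0]
    for f in fields[1:]:
        if f.shape != ref.shape:
            raise ValueError("stacked fields must share a grid")
    valid = np.stack([~f.mask for f in fields])
    vals = np.stack([np.where(f.mask, 0.0, f.values) for f in fields])
    count = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = vals.sum(axis=0) / np.maximum(count, 1)
    mask = count < min_valid_days
    return GriddedField(
        name=f"{ref.name}_seasonal_mean",
        units=ref.units,
        origin_lon=ref.origin_lon,
        origin_lat=ref.origin_lat,
        dlon=ref.dlon,
        dlat=ref.dlat,
        values=np.where(mask, 0.0, mean),
        mask=mask,
    )


def who_exceedance_pct(concentration, standard: float):
    """Percent by which a concentration exceeds an air-quality standard.

    ``(concentration - standard) / standard * 100``; linear in the
    concentration and invariant under joint rescaling of both arguments.
    """
    if standard <= 0:
        raise ValueError("standard must be positive")
    c = np.asarray(concentration, dtype=float)
    out = (c - standard) / standard * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    sd: float  # sample SD (n-1)
    min: float
    max: float
    bin_edges: np.ndarray
    counts: np.ndarray


def descriptive_stats(values, bins: int | Sequence[float] = 20) -> DescriptiveStats:
    """Sample mean, SD (n-1), extremes and histogram counts."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    counts, edges = np.histogram(v, bins=bins)
    return DescriptiveStats(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        min=float(v.min()),
        max=float(v.max()),
        bin_edges=edges,
        counts=counts,
    )


def predict_surface(
    rows: Sequence[ModelRow],
    config: RunConfig,
    fused_aod: GriddedField,
    met: Mapping[str, GriddedField],
    precip_by_date: Mapping[_dt.date, GriddedField],
    day: _dt.date,
    grid_spec: GriddedField,
    k: int | None = None,
) -> GriddedField:
    """Predicted dry PM2.5 on a target grid for one day.

    Each target cell center gets its regressors by the integration access
    rules (AOD from the containing fused pixel, meteorology bilinear,
    previous-local-day precipitation) and a locally calibrated prediction
    from the day's station rows, back-transformed to the dry scale with
    the cell's RH.  Cells with any missing regressor are masked.
    """
    lons, lats = grid_spec.lons(), grid_spec.lats()
    pts, X, rh_list, idx = [], [], [], []
    for i, lat in enumerate(lats):
        for j, lon in enumerate(lons):
            aod = pixel_at(fused_aod, lon, lat)
            if aod is None:
                continue
            vals = {}
            ok = True
            for name in ("pblh", "rh", "st", "ps", "u", "v"):
                v = bilinear_at(met[name], lon, lat)
                if v is None:
                    ok = False
                    break
                vals[name] = v
            if not ok or vals["rh"] > config.rh_cap:
                continue
            try:
                offset = zone_offset(lon, config.tz_edges)
            except ValueError:
                continue
            lp = prev_day_precip(precip_by_date, lon, lat, day, offset)
            if lp is None:
                continue
            ws = float(np.hypot(vals["u"], vals["v"]))
            pts.append((lon, lat))
            X.append(
                [1.0, revise_aod(aod, vals["pblh"]), lp, vals["st"], vals["ps"], ws]
            )
            rh_list.append(vals["rh"])
            idx.append((i, j))
    values = np.zeros(grid_spec.shape)
    mask = np.ones(grid_spec.shape, dtype=bool)
    if pts:
        if k is None:
            k = select_bandwidth(
                rows, config.kernel, (config.k_min, min(config.k_max, len(rows) - 1))
            )
        pred_rev = predict_at(rows, config, np.array(pts), np.array(X), k=k)
        rh_arr = np.array(rh_list)
        pred_dry = np.maximum(pred_rev, 0.0) * (1.0 - rh_arr / 100.0)
        for (i, j), p in zip(idx, pred_dry):
            if np.isfinite(p):
                values[i, j] = p
                mask[i, j] = False
    return GriddedField(
        name="pm25_estimated",
        units="ug/m3",
        origin_lon=grid_spec.origin_lon,
        origin_lat=grid_spec.origin_lat,
        dlon=grid_spec.dlon,
        dlat=grid_spec.dlat,
        values=values,
        mask=mask,
        time=day.isoformat(),
    )


def region_summary(field: GriddedField, standards: Mapping[str, float] | None = None) -> pd.DataFrame:
    """One-row summary of a seasonal surface: stats plus WHO exceedance."""
    standards = standards or {"IT1": WHO_IT1, "IT3": WHO_IT3}
    vals = field.values[~field.mask]
    if vals.size < 2:
        raise ValueError("surface has fewer than 2 valid cells")
    stats = descriptive_stats(vals)
    row = {
        "name": field.name,
        "n_cells": int(vals.size),
        "mean": stats.mean,
        "sd": stats.sd,
        "min": stats.min,
        "max": stats.max,
    }
    for key, std in standards.items():
        row[f"exceedance_{key}_pct"] = who_exceedance_pct(stats.mean, std)
    return pd.DataFrame([row])
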