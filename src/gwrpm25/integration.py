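"""Time-zone-aware collocation of station PM2.5 with AOD and meteorology.

The Aqua overpass is near 13:30 local solar time while the national PM2.5
network time-stamps in Beijing time (UTC+8), and the study domain spans
five nominal 15-degree solar time zones (UTC+5 .. UTC+9).  Station records
are therefore averaged over the 13:00 and 14:00 *local* hours, which map to
Beijing hours ``13 + 8 - offset`` and ``14 + 8 - offset``.

Access rules are deliberately different by variable, matching how the
source products resolve space: AOD is taken from the containing fine pixel
(no interpolation); meteorology is bilinearly interpolated; previous-day
precipitation is read from the grid of the station's previous *local*
calendar date.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import GriddedField, ModelRow, RunConfig, StationRecord
from .physical_corrections import revise_aod, revise_pm25

__all__ = [
    "zone_offset",
    "overpass_hours_beijing",
    "overpass_pm25",
    "bilinear_at",
    "pixel_at",
    "local_date",
    "prev_day_precip",
    "build_model_rows",
]

log = logging.getLogger(__name__)

#: western edges of the five nominal 15-degree bands; offsets +5 .. +9
TZ_EDGES = (67.5, 82.5, 97.5, 112.5, 127.5, 142.5)


def zone_offset(lon: float, edges: Sequence[float] = TZ_EDGES) -> int:
    """UTC offset (+5..+9) of the nominal solar time zone containing ``lon``."""
    for i in range(len(edges) - 1):
        if edges[i] <= lon < edges[i + 1]:
            return 5 + i
    raise ValueError(f"longitude {lon} outside the configured time-zone bands")


def overpass_hours_beijing(offset: int) -> tuple[int, int]:
    """Beijing clock hours corresponding to 13:00 and 14:00 local."""
    return 13 + 8 - offset, 14 + 8 - offset


def overpass_pm25(records: Iterable[StationRecord], offset: int) -> float | None:
    """Average the 13:00/14:00-local PM2.5 records of one station-day.

    If only one of the two hours was reported, that single value is used;
    with neither, the station-day is missing (returns None).
    """
    h1, h2 = overpass_hours_beijing(offset)
    vals = [r.pm25 for r in records if r.hour_beijing in (h1, h2)]
    if not vals:
        return None
    return float(np.mean(vals))


def bilinear_at(field: GriddedField, lon: float, lat: float) -> float | None:
    """Bilinear interpolation from the 4 surrounding cell centers.

    Missing if the point lies outside the convex hull of cell centers or if
    any of the 4 neighbours is masked.
    """
    x = (lon - field.origin_lon) / field.dlon
    y = (lat - field.origin_lat) / field.dlat
    ni, nj = field.shape
    j0 = int(np.floor(x))
    i0 = int(np.floor(y))
    if not (0 <= j0 <= nj - 2 and 0 <= i0 <= ni - 2):
        # tolerate points exactly on the far edge
        if np.isclose(x, nj - 1) and 0 <= i0 <= ni - 2:
            j0 = nj - 2
        elif np.isclose(y, ni - 1) and 0 <= j0 <= nj - 2:
            i0 = ni - 2
        elif np.isclose(x, nj - 1) and np.isclose(y, ni - 1):
            i0, j0 = ni - 2, nj - 2
        else:
            return None
    fx, fy = x - j0, y - i0
    if field.mask[i0 : i0 + 2, j0 : j0 + 2].any():
        return None
    v = field.values
    top = v[i0 + 1, j0] * (1 - fx) + v[i0 + 1, j0 + 1] * fx
    bot = v[i0, j0] * (1 - fx) + v[i0, j0 + 1] * fx
    return float(bot * (1 - fy) + top * fy)


def pixel_at(field: GriddedField, lon: float, lat: float) -> float | None:
    """Value of the cell containing the point (half-open cell membership)."""
    i, j = field.cell_index(lon, lat)
    i, j = int(i), int(j)
    if i < 0:
        return None
    if field.mask[i, j]:
        return None
    return float(field.values[i, j])


def local_date(beijing_date: _dt.date, beijing_hour: int, offset: int) -> _dt.date:
    """Local calendar date of a Beijing-time-stamped instant at UTC+offset."""
    dt = _dt.datetime.combine(beijing_date, _dt.time(beijing_hour)) + _dt.timedelta(
        hours=offset - 8
    )
    return dt.date()


def prev_day_precip(
    precip_by_date: Mapping[_dt.date, GriddedField],
    lon: float,
    lat: float,
    day: _dt.date,
    offset: int,
) -> float | None:
    """Bilinear previous-local-day total precipitation (mm) at a station.

    The 'previous day' is resolved on the station's local calendar date at
    the 13:00-local overpass instant; returns None (row dropped upstream)
    if that date's grid is absent.
    """
    h1, _ = overpass_hours_beijing(offset)
    prev = local_date(day, h1, offset) - _dt.timedelta(days=1)
    grid = precip_by_date.get(prev)
    if grid is None:
        return None
    return bilinear_at(grid, lon, lat)


def build_model_rows(
    fused_aod: GriddedField,
    met: Mapping[str, GriddedField],
    precip_by_date: Mapping[_dt.date, GriddedField],
    stations: Sequence[tuple[str, float, float]],
    records: Iterable[StationRecord],
    day: _dt.date,
    config: RunConfig,
) -> tuple[list[ModelRow], Counter]:
    """Assemble complete-case model rows for one day.

    ``met`` maps variable names ``pblh, rh, st, ps, u, v`` to fields valid
    at the overpass.  Rows missing any ingredient (PM2.5, AOD pixel, a
    meteorological neighbour, previous-day precipitation) are excluded and
    counted by reason; an empty result raises.
    """
    by_station: dict[str, list[StationRecord]] = {}
    for r in records:
        if r.date == day:
            by_station.setdefault(r.station_id, []).append(r)

    rows: list[ModelRow] = []
    excluded: Counter = Counter()
    for sid, lon, lat in stations:
        offset = zone_offset(lon, config.tz_edges)
        pm = overpass_pm25(by_station.get(sid, ()), offset)
        if pm is None:
            excluded["no_pm25"] += 1
            continue
        aod = pixel_at(fused_aod, lon, lat)
        if aod is None:
            excluded["no_aod"] += 1
            continue
        vals = {}
        ok = True
        for name in ("pblh", "rh", "st", "ps", "u", "v"):
            v = bilinear_at(met[name], lon, lat)
            if v is None:
                excluded[f"no_{name}"] += 1
                ok = False
                break
            vals[name] = v
        if not ok:
            continue
        if vals["rh"] > config.rh_cap:
            excluded["rh_above_cap"] += 1
            continue
        lp = prev_day_precip(precip_by_date, lon, lat, day, offset)
        if lp is None:
            excluded["no_prev_precip"] += 1
            continue
        rows.append(
            ModelRow(
                station_id=sid,
                lon=lon,
                lat=lat,
                day=day,
                revised_aod=revise_aod(aod, vals["pblh"]),
                last_prec=lp,
                st=vals["st"],
                ps=vals["ps"],
                ws=float(np.hypot(vals["u"], vals["v"])),
                rh=vals["rh"],
                pblh=vals["pblh"],
                revised_pm25=revise_pm25(pm, vals["rh"], config.rh_cap),
                pm25=pm,
            )
        )
    if not rows:
        raise ValueError(f"no complete-case rows for {day}: {dict(excluded)}")
    if excluded:
        log.info("day %s: %d rows, excluded %s", day, len(rows), dict(excluded))
    return rows, excluded
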