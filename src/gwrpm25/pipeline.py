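"""End-to-end orchestration: synthetic scene -> model rows -> fits and CV.

The functions here wire the stage modules together the way a study run
would: fuse each day's granules, collocate station records, assemble
complete-case rows, and hand them to the GWR and evaluation layers.  They
are what the CLI and the acceptance script drive.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ModelRow, RunConfig
from .integration import build_model_rows
from .synthetic_scene import Scene

__all__ = [
    "config_for_scene",
    "scene_model_rows",
    "rows_to_frame",
    "frame_to_rows",
    "write_rows_csv",
    "read_rows_csv",
]

_ROW_COLUMNS = [
    "station_id", "lon", "lat", "day", "revised_aod", "last_prec",
    "st", "ps", "ws", "rh", "pblh", "revised_pm25", "pm25",
]


def config_for_scene(scene: Scene, **overrides) -> RunConfig:
    """A RunConfig whose domain and RH cap match a generated scene."""
    kw = dict(
        lon_min=scene.config.lon_min,
        lon_max=scene.config.lon_max,
        lat_min=scene.config.lat_min,
        lat_max=scene.config.lat_max,
        rh_cap=scene.config.rh_cap,
        seed=scene.seed,
    )
    kw.update(overrides)
    return RunConfig(**kw)


def scene_model_rows(
    scene: Scene, config: RunConfig | None = None
) -> tuple[dict[_dt.date, list[ModelRow]], Counter]:
    """Run the integration stage over every scene day.

    Returns rows keyed by day plus the pooled exclusion counters.
    """
    config = config or config_for_scene(scene)
    rows_by_day: dict[_dt.date, list[ModelRow]] = {}
    excluded: Counter = Counter()
    for day in scene.dates:
        rows, exc = build_model_rows(
            scene.fused[day],
            scene.met[day],
            scene.precip,
            scene.stations,
            scene.records,
            day,
            config,
        )
        rows_by_day[day] = rows
        excluded.update(exc)
    return rows_by_day, excluded


def rows_to_frame(rows: Sequence[ModelRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "station_id": r.station_id,
                "lon": r.lon,
                "lat": r.lat,
                "day": r.day.isoformat(),
                "revised_aod": r.revised_aod,
                "last_prec": r.last_prec,
                "st": r.st,
                "ps": r.ps,
                "ws": r.ws,
                "rh": r.rh,
                "pblh": r.pblh,
                "revised_pm25": r.revised_pm25,
                "pm25": r.pm25,
            }
            for r in rows
        ],
        columns=_ROW_COLUMNS,
    )


def frame_to_rows(df: pd.DataFrame) -> list[ModelRow]:
    missing = [c for c in _ROW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rows table missing column(s) {missing}")
    return [
        ModelRow(
            station_id=str(r.station_id),
            lon=float(r.lon),
            lat=float(r.lat),
            day=_dt.date.fromisoformat(str(r.day)),
            revised_aod=float(r.revised_aod),
            last_prec=float(r.last_prec),
            st=float(r.st),
            ps=float(r.ps),
            ws=float(r.ws),
            rh=float(r.rh),
            pblh=float(r.pblh),
            revised_pm25=float(r.revised_pm25),
            pm25=float(r.pm25),
        )
        for r in df.itertuples(index=False)
    ]


def write_rows_csv(rows: Sequence[ModelRow], path) -> None:
    rows_to_frame(rows).to_csv(path, index=False)


def read_rows_csv(path) -> list[ModelRow]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return frame_to_rows(pd.read_csv(path))
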