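"""Core domain types, file readers/writers and run configuration.

All geolocated objects share one geographic convention: regular lat-lon
grids, coordinates in decimal degrees referring to cell *centers*, no
projection.  Gridded I/O supports NetCDF (via xarray's scipy backend) and a
long-form CSV dialect (``lon,lat,time,value``) so that test fixtures need no
binary files.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "StationRecord",
    "GriddedField",
    "AODGranule",
    "ModelRow",
    "RunConfig",
    "ValidationError",
    "read_station_csv",
    "write_station_csv",
    "read_grid",
    "write_grid",
    "load_config",
]

#: Known units strings; anything else passes through with a warning.
_KNOWN_UNITS = {
    "ug/m3", "km", "%", "K", "Pa", "m/s", "mm", "1", "", "degrees",
}

STATION_CSV_COLUMNS = ["station_id", "lon", "lat", "date", "hour_beijing", "pm25"]


class ValidationError(ValueError):
    """An input record or file violates a documented invariant."""


@dataclass(frozen=True)
class StationRecord:
    """One station-hour PM2.5 observation, time-stamped in Beijing time (UTC+8).

    ``pm25`` is the dry mass concentration as measured by the station
    instrument (μg/m³), before any hygroscopic correction.
    """

    station_id: str
    lon: float
    lat: float
    date: _dt.date
    hour_beijing: int
    pm25: float

    def __post_init__(self) -> None:
        if not (0 <= self.hour_beijing <= 23):
            raise ValidationError(
                f"hour_beijing must be 0-23, got {self.hour_beijing}"
            )
        if not np.isfinite(self.pm25) or self.pm25 < 0:
            raise ValidationError(f"pm25 must be finite and >= 0, got {self.pm25}")


@dataclass
class GriddedField:
    """A regular lat-lon raster of one variable with a missing-value mask.

    ``values[i, j]`` sits at latitude ``origin_lat + i * dlat`` and longitude
    ``origin_lon + j * dlon`` (cell centers, row 0 southernmost).  ``mask``
    is True where the value is missing.
    """

    name: str
    units: str
    origin_lon: float
    origin_lat: float
    dlon: float
    dlat: float
    values: np.ndarray
    mask: np.ndarray | None = None
    time: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.dlon <= 0 or self.dlat <= 0:
            raise ValidationError("cell sizes must be positive")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask and values must be congruent")
            self.mask = self.mask | ~np.isfinite(self.values)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def lons(self) -> np.ndarray:
        return self.origin_lon + self.dlon * np.arange(self.shape[1])

    def lats(self) -> np.ndarray:
        return self.origin_lat + self.dlat * np.arange(self.shape[0])

    def cell_index(self, lon, lat):
        """Indices of the cell containing (lon, lat).

        Cell membership is half-open: ``[west, east) x [south, north)``, so a
        point on a shared edge belongs to the lower-index cell.  Returns
        integer arrays; out-of-grid points get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        j = np.floor((lon - (self.origin_lon - self.dlon / 2)) / self.dlon).astype(int)
        i = np.floor((lat - (self.origin_lat - self.dlat / 2)) / self.dlat).astype(int)
        ni, nj = self.shape
        bad = (i < 0) | (i >= ni) | (j < 0) | (j >= nj)
        i = np.where(bad, -1, i)
        j = np.where(bad, -1, j)
        return i, j

    def copy_with(self, **kw) -> "GriddedField":
        d = dataclasses.asdict(self)
        d.update(kw)
        # asdict deep-copies arrays into lists only for dataclass members; keep arrays
        d["values"] = np.array(kw.get("values", self.values), dtype=float)
        d["mask"] = np.array(kw.get("mask", self.mask), dtype=bool)
        return GriddedField(**d)


@dataclass
class AODGranule:
    """An AOD-at-550nm field plus per-cell QA flags and an algorithm tag.

    QA follows the MODIS convention 0 = bad, 1 = marginal, 2 = good,
    3 = very good.  Dark Target (DT) granules are nominally 3 km, Deep Blue
    (DB) 10 km.
    """

    field: GriddedField
    qa: np.ndarray
    algorithm: str
    resolution_km: float

    def __post_init__(self) -> None:
        if self.algorithm not in ("DT", "DB"):
            raise ValidationError(f"algorithm must be DT or DB, got {self.algorithm!r}")
        self.qa = np.asarray(self.qa)
        if self.qa.shape != self.field.shape:
            raise ValidationError("QA layer must match field shape")
        defined = ~self.field.mask
        if not np.all((self.qa[defined] >= 0) & (self.qa[defined] <= 3)):
            raise ValidationError("QA flags must be 0-3 wherever AOD is defined")


@dataclass(frozen=True)
class ModelRow:
    """One collocated (location, day) sample carrying every model regressor.

    ``revised_aod`` is the PBLH-normalised AOD (per-km extinction proxy) and
    ``revised_pm25`` the humidity-corrected response; ``pm25`` keeps the raw
    dry overpass average for validation on the measured scale.  Complete-case
    by construction: every regressor is finite.
    """

    station_id: str
    lon: float
    lat: float
    day: _dt.date
    revised_aod: float
    last_prec: float
    st: float
    ps: float
    ws: float
    rh: float
    pblh: float
    revised_pm25: float
    pm25: float

    def __post_init__(self) -> None:
        vals = [self.revised_aod, self.last_prec, self.st, self.ps, self.ws,
                self.rh, self.pblh, self.revised_pm25, self.pm25]
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite regressor in row for {self.station_id}")
        if self.pblh <= 0:
            raise ValidationError("pblh must be positive")


_SUPPORTED_KERNELS = ("bisquare", "gaussian", "uniform")


@dataclass
class RunConfig:
    """Run configuration with documented defaults for every knob.

    Defaults describe the standard analysis: bisquare adaptive-bandwidth
    GWR, leave-one-out bandwidth search over ``k_min..k_max`` neighbours,
    10-fold seasonal cross-validation, relative humidity capped at 95 %
    (the hygroscopic correction diverges at RH -> 100).
    """

    lon_min: float = 95.0
    lon_max: float = 105.0
    lat_min: float = 30.0
    lat_max: float = 40.0
    kernel: str = "bisquare"
    bandwidth_mode: str = "adaptive"
    # adaptive-bandwidth search range: the floor keeps ~6-7 effective
    # observations per parameter after bisquare down-weighting
    k_min: int = 40
    k_max: int = 120
    folds: int = 10
    seed: int = 0
    rh_cap: float = 95.0
    fusion_precedence: str = "DT"
    tz_edges: tuple = (67.5, 82.5, 97.5, 112.5, 127.5, 142.5)
    min_rows: int = 20
    min_valid_days: int = 5
    cv_bandwidth_policy: str = "per-day"
    singular_fallback: str = "missing"

    def __post_init__(self) -> None:
        if self.kernel not in _SUPPORTED_KERNELS:
            raise ValidationError(
                f"unsupported kernel {self.kernel!r}; supported: "
                + ", ".join(_SUPPORTED_KERNELS)
            )
        if not (0 < self.rh_cap < 100):
            raise ValidationError("rh_cap must be in (0, 100)")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.k_min < 8:
            raise ValidationError("k_min must be >= 8 (regressors + 2)")
        if self.lon_min >= self.lon_max or self.lat_min >= self.lat_max:
            raise ValidationError("empty domain")
        if self.cv_bandwidth_policy not in ("per-day", "per-fold"):
            raise ValidationError("cv_bandwidth_policy must be per-day or per-fold")


# ---------------------------------------------------------------------------
# Station CSV I/O


def read_station_csv(path, *, domain=None) -> list[StationRecord]:
    """Read station-hour PM2.5 records from CSV.

    The header must name the columns ``station_id, lon, lat, date,
    hour_beijing, pm25``.  Rows violating record invariants raise
    :class:`ValidationError` naming the offending row numbers.  ``domain``
    optionally bounds (lon_min, lon_max, lat_min, lat_max).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in STATION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")
    records, bad = [], []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is line 1
        try:
            date = _dt.date.fromisoformat(str(row["date"]))
            rec = StationRecord(
                station_id=str(row["station_id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                date=date,
                hour_beijing=int(row["hour_beijing"]),
                pm25=float(row["pm25"]),
            )
        except (ValidationError, ValueError) as exc:
            bad.append((rowno, str(exc)))
            continue
        if domain is not None:
            lo, hi, la, ha = domain
            if not (lo <= rec.lon <= hi and la <= rec.lat <= ha):
                bad.append((rowno, "outside configured domain"))
                continue
        records.append(rec)
    if bad:
        detail = "; ".join(f"row {n}: {m}" for n, m in bad[:10])
        raise ValidationError(f"{path}: {len(bad)} invalid row(s): {detail}")
    return records


def write_station_csv(records: Iterable[StationRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "station_id": r.station_id,
                "lon": r.lon,
                "lat": r.lat,
                "date": r.date.isoformat(),
                "hour_beijing": r.hour_beijing,
                "pm25": r.pm25,
            }
            for r in records
        ],
        columns=STATION_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gridded I/O


def _check_units(units: str) -> None:
    if units not in _KNOWN_UNITS:
        warnings.warn(f"unknown units string {units!r}; passing through", stacklevel=3)


def write_grid(fld: GriddedField, path) -> None:
    """Write a GriddedField to NetCDF (``.nc``) or long-form CSV."""
    path = Path(path)
    if path.suffix == ".csv":
        lon2, lat2 = np.meshgrid(fld.lons(), fld.lats())
        vals = np.where(fld.mask, np.nan, fld.values)
        df = pd.DataFrame(
            {
                "lon": lon2.ravel(),
                "lat": lat2.ravel(),
                "time": fld.time or "",
                "value": vals.ravel(),
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# name={fld.name} units={fld.units}\n")
            df.to_csv(fh, index=False)
        return
    da = xr.DataArray(
        np.where(fld.mask, np.nan, fld.values),
        coords={"lat": fld.lats(), "lon": fld.lons()},
        dims=("lat", "lon"),
        name=fld.name or "value",
        attrs={"units": fld.units, "time": fld.time or ""},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_grid(path) -> GriddedField:
    """Read a GriddedField written by :func:`write_grid` (exact round trip)."""
    path = Path(path)
    if path.suffix == ".csv":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
            df = pd.read_csv(fh)
        lons = np.unique(df["lon"].to_numpy())
        lats = np.unique(df["lat"].to_numpy())
        if len(df) != len(lons) * len(lats):
            raise ValidationError(
                f"{path}: {len(df)} rows != grid size {len(lons)}x{len(lats)}"
            )
        vals = (
            df.pivot_table(index="lat", columns="lon", values="value", dropna=False)
            .reindex(index=lats, columns=lons)
            .to_numpy()
        )
        times = df["time"].dropna().unique()
        time = str(times[0]) if len(times) and str(times[0]) else None
        name, units = meta.get("name", "value"), meta.get("units", "")
    else:
        ds = xr.open_dataset(path, engine="scipy")
        name = next(iter(ds.data_vars))
        da = ds[name]
        lats = da["lat"].to_numpy()
        lons = da["lon"].to_numpy()
        vals = da.to_numpy()
        units = da.attrs.get("units", "")
        time = da.attrs.get("time") or None
        ds.close()
    if len(lons) < 2 or len(lats) < 2:
        raise ValidationError(f"{path}: grid must span at least 2 cells per axis")
    dlon = float(np.diff(lons).mean())
    dlat = float(np.diff(lats).mean())
    if not (np.allclose(np.diff(lons), dlon) and np.allclose(np.diff(lats), dlat)):
        raise ValidationError(f"{path}: coordinates are not a regular grid")
    _check_units(units)
    return GriddedField(
        name=name,
        units=units,
        origin_lon=float(lons[0]),
        origin_lat=float(lats[0]),
        dlon=dlon,
        dlat=dlat,
        values=np.nan_to_num(vals, nan=0.0),
        mask=~np.isfinite(vals),
        time=time,
    )


def write_granule(granule: AODGranule, path) -> None:
    """Write an AOD granule (value + QA + algorithm tag) to NetCDF."""
    fld = granule.field
    ds = xr.Dataset(
        {
            "aod": (("lat", "lon"), np.where(fld.mask, np.nan, fld.values)),
            "qa": (("lat", "lon"), granule.qa.astype(np.int32)),
        },
        coords={"lat": fld.lats(), "lon": fld.lons()},
        attrs={
            "units": fld.units,
            "time": fld.time or "",
            "algorithm": granule.algorithm,
            "resolution_km": granule.resolution_km,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_granule(path) -> AODGranule:
    ds = xr.open_dataset(path, engine="scipy")
    lats = ds["lat"].to_numpy()
    lons = ds["lon"].to_numpy()
    vals = ds["aod"].to_numpy()
    qa = ds["qa"].to_numpy()
    fld = GriddedField(
        name="aod",
        units=str(ds.attrs.get("units", "1")),
        origin_lon=float(lons[0]),
        origin_lat=float(lats[0]),
        dlon=float(np.diff(lons).mean()),
        dlat=float(np.diff(lats).mean()),
        values=np.nan_to_num(vals, nan=0.0),
        mask=~np.isfinite(vals),
        time=str(ds.attrs.get("time")) or None,
    )
    granule = AODGranule(
        field=fld,
        qa=qa,
        algorithm=str(ds.attrs["algorithm"]),
        resolution_km=float(ds.attrs.get("resolution_km", 0.0)),
    )
    ds.close()
    return granule


# ---------------------------------------------------------------------------
# Run configuration


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a key-value file plus overrides.

    The file holds ``key = value`` lines (``#`` comments allowed).  Unknown
    keys raise; overrides win over file values; absent keys take defaults.
    """
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kw: dict = {}

    def _coerce(key, raw):
        if key not in fields:
            raise ValidationError(f"unknown config key {key!r}")
        typ = fields[key].type
        if isinstance(raw, str):
            raw = raw.strip()
            if typ in ("int",):
                return int(raw)
            if typ in ("float",):
                return float(raw)
            if typ == "tuple":
                return tuple(float(x) for x in raw.split(","))
            return raw
        return raw

    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key = value")
            key, raw = (tok.strip() for tok in line.split("=", 1))
            kw[key] = _coerce(key, raw)
    for key, val in (overrides or {}).items():
        kw[key] = _coerce(key, val)
    return RunConfig(**kw)
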