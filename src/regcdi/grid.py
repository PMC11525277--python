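"""Gridded monthly data model, raster-stack and table I/O.

All analysis operates on monthly (time, row, col) stacks.  Row 0 is the
northernmost row; pixel coordinates are pixel centers; the resolution tag
("0.25deg", "1deg", ...) is metadata only — no reprojection is performed
and every stack entering one analysis must already be co-registered.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "GridError", "AlignmentError", "GriddedSeries", "ZoneMap", "YieldTable",
    "SeasonDefinition", "KHARIF", "RABI", "SUMMER",
    "read_grid_stack", "write_grid_stack", "read_yield_table",
    "write_yield_table", "assert_aligned",
]


class GridError(ValueError):
    """Malformed gridded data or unreadable stack."""


class AlignmentError(GridError):
    """Stacks with different shapes or timestamps were combined."""


def _validate_timestamps(timestamps: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    ts = [(int(y), int(m)) for y, m in timestamps]
    for y, m in ts:
        if not 1 <= m <= 12:
            raise GridError(f"month out of range in timestamp {(y, m)}")
    keys = [y * 12 + (m - 1) for y, m in ts]
    if any(b <= a for a, b in zip(keys, keys[1:])):
        raise GridError("timestamps must be strictly increasing")
    return ts


@dataclass
class GriddedSeries:
    """A (time, row, col) monthly raster stack for one variable.

    ``mask`` is True where a cell is missing; values must be finite
    wherever the mask is False.  Missing cells propagate through all
    arithmetic and are excluded from climatologies.
    """

    values: np.ndarray
    timestamps: list[tuple[int, int]]
    variable: str = "var"
    units: str = ""
    mask: np.ndarray | None = None
    resolution: str = "0.25deg"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GridError("values must be a (time, row, col) array")
        self.timestamps = _validate_timestamps(self.timestamps)
        if len(self.timestamps) != self.values.shape[0]:
            raise GridError("timestamps length must match the time axis")
        if self.mask is None:
            # NaN is the conventional missing marker; infinities are corrupt
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise GridError("mask shape must match values shape")
            self.mask = self.mask | np.isnan(self.values)
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise GridError("values must be finite wherever unmasked")

    # -- convenience -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1..12) for every time step."""
        return np.array([m for _, m in self.timestamps])

    @property
    def years(self) -> np.ndarray:
        return np.array([y for y, _ in self.timestamps])

    @property
    def n_years(self) -> int:
        return len(np.unique(self.years))

    def masked(self) -> np.ndarray:
        """Values with missing cells as NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def replace(self, values: np.ndarray, *, variable: str | None = None,
                units: str | None = None, mask: np.ndarray | None = None,
                timestamps: list[tuple[int, int]] | None = None) -> "GriddedSeries":
        """A copy of this series with new values (and optionally new metadata)."""
        return GriddedSeries(
            values=values,
            timestamps=self.timestamps if timestamps is None else timestamps,
            variable=self.variable if variable is None else variable,
            units=self.units if units is None else units,
            mask=self.mask.copy() if mask is None else mask,
            resolution=self.resolution,
        )

    def select_times(self, idx: np.ndarray) -> "GriddedSeries":
        """Subset along the time axis (boolean or integer index)."""
        idx = np.asarray(idx)
        positions = np.flatnonzero(idx) if idx.dtype == bool else idx
        return GriddedSeries(
            values=self.values[positions],
            timestamps=[self.timestamps[i] for i in positions],
            variable=self.variable,
            units=self.units,
            mask=self.mask[positions],
            resolution=self.resolution,
        )


def assert_aligned(*series: GriddedSeries) -> None:
    """Fail loudly when stacks in one analysis are not co-registered."""
    ref = series[0]
    for s in series[1:]:
        if s.shape != ref.shape:
            raise AlignmentError(f"shape mismatch: {s.shape} vs {ref.shape}")
        if s.timestamps != ref.timestamps:
            raise AlignmentError("timestamp mismatch between stacks")


@dataclass
class ZoneMap:
    """Per-pixel district/zone labels; 0 (or ``background``) = no zone."""

    labels: np.ndarray
    background: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise GridError("zone labels must be a (row, col) array")

    @property
    def zone_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != self.background]

    def pixels(self, zone: int) -> np.ndarray:
        return self.labels == zone


@dataclass
class YieldTable:
    """District-year crop yield records (mass per area).

    Standardization (z per district) is added by
    :func:`regcdi.validation.standardize_yield`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"district", "year", "yield"}
        missing = required - set(self.data.columns)
        if missing:
            raise GridError(f"yield table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["district", "year"])
        if dup.any():
            raise GridError("duplicate (district, year) rows in yield table")
        self.data = self.data.reset_index(drop=True)

    @property
    def districts(self) -> np.ndarray:
        return self.data["district"].unique()

    def district_series(self, district: int, column: str = "yield") -> pd.Series:
        sub = self.data[self.data["district"] == district].set_index("year")
        return sub[column].dropna().sort_index()


@dataclass(frozen=True)
class SeasonDefinition:
    """A named cropping season as a set of calendar months."""

    name: str
    months: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        months = frozenset(int(m) for m in self.months)
        if not months:
            raise GridError(f"season {self.name!r} has an empty month set")
        if not months <= set(range(1, 13)):
            raise GridError(f"season {self.name!r} has months outside 1..12")
        object.__setattr__(self, "months", months)


# Odisha cropping calendar: pre-monsoon summer, monsoon Kharif
# (sowing Jun/Jul, harvest Sep/Oct), winter Rabi (Oct/Nov-Jan/Feb).
SUMMER = SeasonDefinition("summer", frozenset({3, 4, 5, 6}))
KHARIF = SeasonDefinition("kharif", frozenset({6, 7, 8, 9}))
RABI = SeasonDefinition("rabi", frozenset({10, 11, 12, 1, 2}))


# ---------------------------------------------------------------------------
# Raster-stack I/O
# ---------------------------------------------------------------------------

def _to_dataset(series: GriddedSeries) -> xr.Dataset:
    time = np.array([np.datetime64(f"{y:04d}-{m:02d}-01") for y, m in series.timestamps])
    da = xr.DataArray(
        series.masked(),
        dims=("time", "lat", "lon"),
        coords={
            "time": time,
            "lat": np.arange(series.grid_shape[0], dtype=float),
            "lon": np.arange(series.grid_shape[1], dtype=float),
        },
        name=series.variable,
        attrs={"units": series.units, "resolution": series.resolution},
    )
    return da.to_dataset()


def write_grid_stack(series: GriddedSeries, path: str | Path) -> None:
    """Write a stack to NetCDF (``.nc``) or a TIFF-per-month directory.

    Missing cells are stored as NaN; :func:`read_grid_stack` recovers the
    mask from them.
    """
    path = Path(path)
    if path.suffix == ".nc":
        ds = _to_dataset(series)
        ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")
        return
    # TIFF directory dialect: one single-band float TIFF per month.
    import tifffile

    path.mkdir(parents=True, exist_ok=True)
    for i, (y, m) in enumerate(series.timestamps):
        sl = series.values[i].astype(np.float64).copy()
        sl[series.mask[i]] = np.nan
        tifffile.imwrite(path / f"{series.variable}_{y:04d}-{m:02d}.tif", sl)


_TIF_RE = re.compile(r"_(\d{4})-(\d{2})\.tif$")


def read_grid_stack(path: str | Path, variable: str | None = None) -> GriddedSeries:
    """Read a raster stack written by :func:`write_grid_stack`.

    A NetCDF file needs a ``time`` dimension; an unordered time axis is
    reordered ascending with a logged notice.  A directory is treated as
    the TIFF-per-month dialect with timestamps parsed from file names.
    """
    path = Path(path)
    if not path.exists():
        raise GridError(f"no such raster stack: {path}")
    if path.is_dir():
        return _read_tiff_dir(path, variable)
    try:
        ds = xr.open_dataset(path, engine="scipy")
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise GridError(f"unreadable NetCDF stack {path}: {exc}") from exc
    with ds:
        if "time" not in ds.dims:
            raise GridError(f"stack {path} has no time dimension")
        if variable is None:
            data_vars = [v for v in ds.data_vars if "time" in ds[v].dims]
            if len(data_vars) != 1:
                raise GridError(
                    f"stack {path} has variables {list(ds.data_vars)}; specify one")
            variable = data_vars[0]
        if variable not in ds:
            raise GridError(f"variable {variable!r} not in stack {path}")
        da = ds[variable].transpose("time", "lat", "lon").load()
    time = pd.to_datetime(da["time"].values)
    order = np.argsort(time.values)
    if not np.array_equal(order, np.arange(len(order))):
        logger.warning("time axis of %s was unordered; sorted ascending", path)
        da = da.isel(time=order)
        time = time[order]
    timestamps = [(t.year, t.month) for t in time]
    values = np.asarray(da.values, dtype=float)
    return GriddedSeries(
        values=values,
        timestamps=timestamps,
        variable=variable,
        units=str(da.attrs.get("units", "")),
        mask=~np.isfinite(values),
        resolution=str(da.attrs.get("resolution", "0.25deg")),
    )


def _read_tiff_dir(path: Path, variable: str | None) -> GriddedSeries:
    import tifffile

    pattern = f"{variable}_*.tif" if variable else "*.tif"
    files = sorted(path.glob(pattern))
    if not files:
        raise GridError(f"no TIFF slices matching {pattern!r} under {path}")
    stamped = []
    for f in files:
        m = _TIF_RE.search(f.name)
        if m is None:
            raise GridError(f"cannot parse timestamp from {f.name}")
        stamped.append(((int(m.group(1)), int(m.group(2))), f))
    stamped.sort(key=lambda t: t[0])
    values = np.stack([tifffile.imread(f) for _, f in stamped]).astype(float)
    name = variable or files[0].name.rsplit("_", 1)[0]
    return GriddedSeries(values=values, timestamps=[ts for ts, _ in stamped],
                         variable=name)


# ---------------------------------------------------------------------------
# Yield table I/O
# ---------------------------------------------------------------------------

def read_yield_table(path: str | Path) -> YieldTable:
    """Read a district/year/yield CSV.

    Rows with a blank or non-parsable yield are kept but flagged missing
    (NaN) and excluded from downstream means and standard deviations.
    A non-numeric entry other than blank raises.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"district", "year", "yield"}
    missing = required - set(df.columns)
    if missing:
        raise GridError(f"yield table {path} missing columns: {sorted(missing)}")
    raw = df["yield"]
    parsed = pd.to_numeric(raw, errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        raise GridError(f"non-numeric yield values in {path}: "
                        f"{raw[bad].tolist()[:5]}")
    if parsed.isna().any():
        logger.warning("%d yield rows flagged missing in %s", parsed.isna().sum(), path)
    df = df.assign(**{"yield": parsed})
    df["district"] = df["district"].astype(int)
    df["year"] = df["year"].astype(int)
    return YieldTable(df[["district", "year", "yield"]])


def write_yield_table(table: YieldTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)
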