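"""Shared domain types, file readers/writers, and coordinate conventions.

Conventions used throughout the package:

* horizontal coordinates are planar meters (UTM-like easting/northing);
  geographic degrees are never accepted,
* depth is meters below the surface, positive down,
* timestamps are UTC seconds since the epoch; daily binning applies a
  configurable fixed offset (``day_boundary_offset``),
* voxel indices are 0-based with half-open intervals
  ``[origin + i*L, origin + (i+1)*L)``.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pathvol")

SEASONS = ("spring", "summer", "fall", "winter")

POSITION_COLUMNS = ("fish_id", "timestamp", "x", "y", "depth", "hpe")


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Position:
    """One solved telemetry fix.

    Parameters
    ----------
    fish_id : str
        Opaque transmitter/fish identifier.
    t : float
        UTC seconds since epoch.
    x, y : float
        Planar meters (east, north).
    depth : float
        Meters below surface, >= 0 (positive down).
    hpe : float
        Unitless hyperbolic-positioning-error score, >= 0.
    """

    fish_id: str
    t: float
    x: float
    y: float
    depth: float
    hpe: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.hpe < 0:
            raise ValueError(f"hpe must be >= 0, got {self.hpe}")


@dataclass
class Bathymetry:
    """Regular lake-depth grid; cells outside the shoreline are NaN.

    ``depth`` is indexed ``[row, col]`` with row 0 at the *north* edge
    (the ESRI ASCII convention); ``origin_x/origin_y`` give the lower-left
    corner of the grid.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    depth: np.ndarray  # (n_rows, n_cols), NaN outside the lake

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.depth = np.asarray(self.depth, dtype=float)
        in_lake = np.isfinite(self.depth)
        if np.any(self.depth[in_lake] < 0):
            raise ValueError("in-lake depths must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.depth.shape[0]

    @property
    def n_cols(self) -> int:
        return self.depth.shape[1]

    @property
    def max_depth(self) -> float:
        return float(np.nanmax(self.depth))

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def lake_area(self) -> float:
        """Area of in-lake cells, m^2."""
        return float(np.isfinite(self.depth).sum() * self.cell_area)

    @property
    def lake_volume(self) -> float:
        """Total lake volume, m^3 (sum of cell area x depth)."""
        return float(np.nansum(self.depth) * self.cell_area)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid bounding box."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_index(self, x, y):
        """(row, col) of the cell containing (x, y); may be out of range."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor(
            (np.asarray(y) - self.origin_y) / self.cell_size
        ).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def depth_at(self, x, y):
        """Lake depth at planar point(s); NaN outside the grid or shoreline."""
        scalar = np.ndim(x) == 0 and np.ndim(y) == 0
        xa = np.atleast_1d(np.asarray(x, dtype=float))
        ya = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.cell_index(xa, ya)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.full(xa.shape, np.nan)
        out[inside] = self.depth[row[inside], col[inside]]
        return float(out[0]) if scalar else out


@dataclass
class TemperatureSeries:
    """Contiguous daily mean surface (<6 m) temperature plus ice phenology."""

    dates: list[_dt.date]
    surface_temp: np.ndarray  # degrees C, one per date
    ice_on: _dt.date
    ice_off: _dt.date

    def __post_init__(self) -> None:
        self.surface_temp = np.asarray(self.surface_temp, dtype=float)
        if len(self.dates) != len(self.surface_temp):
            raise ValueError("dates and surface_temp must align")
        if self.ice_on == self.ice_off:
            raise ValueError("ice_on must differ from ice_off")
        for a, b in zip(self.dates[:-1], self.dates[1:]):
            if (b - a).days != 1:
                raise ValueError("temperature series must be contiguous daily")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "surface_temp": self.surface_temp})


@dataclass
class Config:
    """Analysis parameters; defaults follow the study design this package
    re-implements (20 m voxels, x100 vertical rescale, HPE<=20 filter,
    2 m depth buffer, 1080 s gap rule, 95% isopleth)."""

    voxel_length: float = 20.0       # m, horizontal voxel side
    rescale: float = 100.0           # vertical rescale factor (z_rescaled = z*rescale)
    hpe_max: float = 20.0            # positions with hpe > hpe_max are removed
    depth_buffer: float = 2.0        # m beyond local lake depth allowed
    max_gap: float = 1080.0          # s; longer segment gaps contribute no volume
    vswim_quantile: float = 0.50     # one of 0.50, 0.75, 0.95, 1.00
    vswim_mode: str = "fish_season"  # "pooled" or "fish_season"
    isopleth_level: float = 0.95
    day_boundary_offset: float = 0.0  # s added to t before daily binning
    volume_threshold: int = 1        # voxel counted as used when count >= threshold
    kud_bandwidth: str = "silverman"  # "silverman" or "scott"
    min_kud_positions: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.isopleth_level <= 1:
            raise ValueError("isopleth_level must be in (0, 1]")
        for name in ("voxel_length", "rescale", "hpe_max", "depth_buffer", "max_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.vswim_mode not in ("pooled", "fish_season"):
            raise ValueError("vswim_mode must be 'pooled' or 'fish_season'")

    @property
    def voxel_z(self) -> float:
        return self.voxel_length / self.rescale

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Position I/O
# ---------------------------------------------------------------------------

def read_positions(path: str | Path) -> list[Position]:
    """Read a delimited-text position file into time-sorted :class:`Position`.

    The file must have header columns fish_id, timestamp (ISO 8601), x, y,
    depth, hpe.  Rows with missing or non-numeric fields are rejected and the
    count logged; output is sorted by (fish_id, t).
    """
    df = pd.read_csv(path)
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"position file {path} missing required columns: {missing}")
    n_raw = len(df)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    num = df[["x", "y", "depth", "hpe"]].apply(pd.to_numeric, errors="coerce")
    ok = ts.notna() & num.notna().all(axis=1) & df["fish_id"].notna()
    ok &= (num["depth"] >= 0) & (num["hpe"] >= 0)
    n_rejected = int(n_raw - ok.sum())
    if n_rejected:
        logger.warning("read_positions: rejected %d of %d rows", n_rejected, n_raw)
    kept = df[ok]
    out = [
        Position(
            fish_id=str(fid),
            t=float(t.timestamp()),
            x=float(x), y=float(y), depth=float(d), hpe=float(h),
        )
        for fid, t, x, y, d, h in zip(
            kept["fish_id"], ts[ok], num.loc[ok, "x"], num.loc[ok, "y"],
            num.loc[ok, "depth"], num.loc[ok, "hpe"],
        )
    ]
    out.sort(key=lambda p: (p.fish_id, p.t))
    return out


def write_positions(positions: Iterable[Position], path: str | Path) -> None:
    rows = [
        {
            "fish_id": p.fish_id,
            "timestamp": _dt.datetime.fromtimestamp(p.t, tz=_dt.timezone.utc)
            .isoformat().replace("+00:00", "Z"),
            "x": f"{p.x:.3f}",
            "y": f"{p.y:.3f}",
            "depth": f"{p.depth:.3f}",
            "hpe": f"{p.hpe:.3f}",
        }
        for p in positions
    ]
    pd.DataFrame(rows, columns=list(POSITION_COLUMNS)).to_csv(path, index=False)


def positions_to_frame(positions: Sequence[Position]) -> pd.DataFrame:
    """Columnar view of a position list (fish_id, t, x, y, depth, hpe)."""
    return pd.DataFrame(
        {
            "fish_id": [p.fish_id for p in positions],
            "t": [p.t for p in positions],
            "x": [p.x for p in positions],
            "y": [p.y for p in positions],
            "depth": [p.depth for p in positions],
            "hpe": [p.hpe for p in positions],
        }
    )


# ---------------------------------------------------------------------------
# Bathymetry I/O (ESRI ASCII grid + plain CSV grid)
# ---------------------------------------------------------------------------

def read_bathymetry(path: str | Path) -> Bathymetry:
    """Read an ESRI-ASCII-style grid of lake depths (m, positive down).

    Header keys: ncols, nrows, xllcorner, yllcorner, cellsize, nodata_value.
    Nodata cells are outside the shoreline.  Negative in-lake depth is fatal.
    """
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append(line)
    required = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
    missing = [k for k in required if k not in header]
    if missing:
        raise ValueError(f"bathymetry {path} missing header keys: {missing}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(data_lines, dtype=float)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    depth = np.where(values == nodata, np.nan, values)
    return Bathymetry(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        depth=depth,
    )


def write_bathymetry(bathy: Bathymetry, path: str | Path,
                     nodata: float = -9999.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {bathy.n_cols}\n")
        fh.write(f"nrows {bathy.n_rows}\n")
        fh.write(f"xllcorner {bathy.origin_x:.6f}\n")
        fh.write(f"yllcorner {bathy.origin_y:.6f}\n")
        fh.write(f"cellsize {bathy.cell_size:.6f}\n")
        fh.write(f"nodata_value {nodata:.1f}\n")
        filled = np.where(np.isfinite(bathy.depth), bathy.depth, nodata)
        for row in filled:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


def read_bathymetry_csv(path: str | Path, origin_x: float, origin_y: float,
                        cell_size: float) -> Bathymetry:
    """Plain CSV depth grid (row 0 = north edge, empty cells outside lake)."""
    depth = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return Bathymetry(origin_x=origin_x, origin_y=origin_y,
                      cell_size=cell_size, depth=depth)


# ---------------------------------------------------------------------------
# Temperature I/O
# ---------------------------------------------------------------------------

def read_temperature(path: str | Path, ice_on: _dt.date | str,
                     ice_off: _dt.date | str) -> TemperatureSeries:
    """Delimited text with columns date (ISO), surface_temp; plus ice dates."""
    df = pd.read_csv(path)
    for col in ("date", "surface_temp"):
        if col not in df.columns:
            raise ValueError(f"temperature file missing column {col!r}")
    dates = [d.date() for d in pd.to_datetime(df["date"])]
    if isinstance(ice_on, str):
        ice_on = _dt.date.fromisoformat(ice_on)
    if isinstance(ice_off, str):
        ice_off = _dt.date.fromisoformat(ice_off)
    return TemperatureSeries(
        dates=dates,
        surface_temp=df["surface_temp"].to_numpy(dtype=float),
        ice_on=ice_on,
        ice_off=ice_off,
    )


def write_temperature(series: TemperatureSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "date": [d.isoformat() for d in series.dates],
            "surface_temp": [f"{t:.3f}" for t in series.surface_temp],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sparse voxel I/O
# ---------------------------------------------------------------------------

def write_sparse_voxels(daily_ppv, path: str | Path) -> None:
    """Write one fish-day's voxel counts as rows (ix, iy, iz, count >= 1).

    Grid dims are recorded in a comment so the file round-trips losslessly
    with :func:`read_sparse_voxels`.
    """
    nx, ny, nz = daily_ppv.dims
    with open(path, "w") as fh:
        fh.write(f"# dims {nx} {ny} {nz}\n")
        fh.write(f"# fish_id {daily_ppv.fish_id} date {daily_ppv.date.isoformat()} "
                 f"n_segments {daily_ppv.n_segments}\n")
        fh.write("ix,iy,iz,count\n")
        order = np.argsort(daily_ppv.voxels)
        for flat, count in zip(daily_ppv.voxels[order], daily_ppv.counts[order]):
            ix, iy, iz = np.unravel_index(int(flat), (nx, ny, nz))
            fh.write(f"{ix},{iy},{iz},{int(count)}\n")


def read_sparse_voxels(path: str | Path):
    """Read a sparse voxel file -> (flat voxel indices, counts, dims)."""
    dims = None
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# dims"):
            dims = tuple(int(v) for v in line.split()[2:5])
            break
    if dims is None:
        raise ValueError(f"sparse voxel file {path} lacks a '# dims' header")
    body = [ln for ln in lines if not ln.startswith("#")]
    df = pd.read_csv(pd.io.common.StringIO("".join(body)))
    flat = np.ravel_multi_index(
        (df["ix"].to_numpy(dtype=np.int64), df["iy"].to_numpy(dtype=np.int64),
         df["iz"].to_numpy(dtype=np.int64)), dims
    )
    return flat.astype(np.int64), df["count"].to_numpy(dtype=np.int64), dims
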