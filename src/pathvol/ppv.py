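"""Potential path volume (PPV) on a vertically rescaled voxel grid.

The study volume is discretized into voxels of horizontal side ``L`` and
vertical side ``L / rescale`` meters, so that after multiplying depth by the
rescale factor every voxel is a cube of side ``L``; the fine vertical
resolution captures the narrow depth band a benthic fish occupies.  A path
segment's PPV is the set of in-lake voxels whose centers lie inside the
prolate spheroid with the two fixes as foci and major axis ``v * dt`` —
every point the fish could have reached while traveling at speed ``v``
between the fixes.  Summing segment PPVs over a day gives per-voxel
inclusion counts, from which the daily habitat volume (used voxels times
voxel volume) and relative-use summaries derive.

The ellipsoid, the observed segment speed, and the swim-speed parameter all
live in *real* meters: v_swim is a quantile of observed daily movement
rates measured in m/s, so the speed budget ``v * dt`` is a real distance
and the degeneracy test (v_obs >= v_swim) compares like with like.  The
vertical rescale factor is a discretization and kernel-scaling device, not
a change of movement metric.  Out-of-lake portions of an ellipsoid are
clipped by the lake mask.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import Bathymetry, Position
from .preprocess import PathSegment, adjust_vswim

logger = logging.getLogger("pathvol")


# ---------------------------------------------------------------------------
# Voxel grid
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """The discretized, vertically rescaled study volume with a lake mask.

    Voxel (ix, iy, iz) spans, in real units,
    ``[x0+ix*L, x0+(ix+1)*L) x [y0+iy*L, y0+(iy+1)*L)`` horizontally and
    ``[iz*voxel_z, (iz+1)*voxel_z)`` in depth; in rescaled units it is a cube
    of side L.  ``lake_mask[ix, iy, iz]`` is True iff the voxel center is
    inside the shoreline and its center depth does not exceed the local lake
    depth.  The grid geometry is fixed once per study area.
    """

    origin: tuple[float, float, float]  # (x0, y0, 0) in real meters
    voxel_length: float                 # L, m (horizontal side)
    rescale: float
    dims: tuple[int, int, int]          # (nx, ny, nz)
    lake_mask: np.ndarray               # bool, shape dims

    @property
    def voxel_z(self) -> float:
        """Vertical voxel side in real meters (= L / rescale)."""
        return self.voxel_length / self.rescale

    @property
    def voxel_volume(self) -> float:
        """Real-world voxel volume, m^3 (= L * L * L/rescale)."""
        return self.voxel_length ** 2 * self.voxel_z

    @property
    def n_lake_voxels(self) -> int:
        return int(self.lake_mask.sum())

    @property
    def masked_volume(self) -> float:
        """Total volume of in-mask voxels, m^3."""
        return self.n_lake_voxels * self.voxel_volume

    def axis_centers_rescaled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates per axis, in the rescaled metric."""
        L = self.voxel_length
        nx, ny, nz = self.dims
        cx = self.origin[0] + (np.arange(nx) + 0.5) * L
        cy = self.origin[1] + (np.arange(ny) + 0.5) * L
        cz = (np.arange(nz) + 0.5) * L  # rescaled depth; real depth = cz/rescale
        return cx, cy, cz

    def axis_centers_real(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates per axis, in real meters (depth for z)."""
        cx, cy, cz = self.axis_centers_rescaled()
        return cx, cy, cz / self.rescale

    def to_rescaled(self, p: Position) -> np.ndarray:
        """Map a position to the rescaled working space (x, y, depth*rescale)."""
        return np.array([p.x, p.y, p.depth * self.rescale], dtype=float)

    def to_real(self, p: Position) -> np.ndarray:
        """Map a position to real-space coordinates (x, y, depth)."""
        return np.array([p.x, p.y, p.depth], dtype=float)

    def flat(self, ix, iy, iz):
        return np.ravel_multi_index((ix, iy, iz), self.dims)


def build_voxel_grid(
    bathymetry: Bathymetry,
    voxel_length: float = 20.0,
    rescale: float = 100.0,
) -> VoxelGrid:
    """Voxelize the bathymetry bounding box; mask voxels by shoreline/depth.

    A voxel is in the lake mask iff the lake depth at its horizontal center
    is defined (inside the shoreline) and the voxel's center depth is at most
    that lake depth.  A voxel length below the bathymetry resolution earns a
    warning (the depth lookup is then coarser than the voxels).
    """
    if voxel_length <= 0:
        raise ValueError("voxel_length must be > 0")
    if rescale < 1:
        raise ValueError("rescale must be >= 1")
    if voxel_length < bathymetry.cell_size:
        logger.warning(
            "voxel_length %.1f m is finer than the bathymetry resolution %.1f m",
            voxel_length, bathymetry.cell_size)
    xmin, ymin, xmax, ymax = bathymetry.extent
    L = voxel_length
    nx = int(np.ceil((xmax - xmin) / L))
    ny = int(np.ceil((ymax - ymin) / L))
    max_depth = bathymetry.max_depth
    voxel_z = L / rescale
    nz = max(1, int(np.ceil(max_depth / voxel_z)))
    cx = xmin + (np.arange(nx) + 0.5) * L
    cy = ymin + (np.arange(ny) + 0.5) * L
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    lake_depth = bathymetry.depth_at(gx.ravel(), gy.ravel()).reshape(nx, ny)
    center_depth = (np.arange(nz) + 0.5) * voxel_z
    with np.errstate(invalid="ignore"):
        mask = center_depth[np.newaxis, np.newaxis, :] <= lake_depth[:, :, np.newaxis]
    mask &= np.isfinite(lake_depth)[:, :, np.newaxis]
    return VoxelGrid(
        origin=(xmin, ymin, 0.0),
        voxel_length=L,
        rescale=rescale,
        dims=(nx, ny, nz),
        lake_mask=mask,
    )


# ---------------------------------------------------------------------------
# Ellipsoid inclusion
# ---------------------------------------------------------------------------

def ellipsoid_contains(f1, f2, v: float, dt: float, p) -> bool:
    """True iff |p-f1| + |p-f2| <= v*dt (boundary inclusive).

    All points are in the rescaled metric.  Raises if the foci are farther
    apart than the speed budget allows (the caller must have applied
    :func:`~pathvol.preprocess.adjust_vswim` first).
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    p = np.asarray(p, dtype=float)
    budget = v * dt
    focal = float(np.linalg.norm(f2 - f1))
    if focal > budget * (1 + 1e-12):
        raise ValueError(
            f"degenerate segment: focal distance {focal:.6g} exceeds speed "
            f"budget v*dt = {budget:.6g}; apply adjust_vswim first")
    return float(np.linalg.norm(p - f1) + np.linalg.norm(p - f2)) <= budget


def _candidate_box(grid: VoxelGrid, center: np.ndarray, half: float):
    """Index ranges of voxels whose centers may fall within ``half`` meters
    of ``center`` along each axis (real-space coordinates)."""
    L = grid.voxel_length
    vz = grid.voxel_z
    ox, oy, _ = grid.origin
    nx, ny, nz = grid.dims
    lo = [
        int(np.floor((center[0] - half - ox) / L - 0.5)),
        int(np.floor((center[1] - half - oy) / L - 0.5)),
        int(np.floor((center[2] - half) / vz - 0.5)),
    ]
    hi = [
        int(np.ceil((center[0] + half - ox) / L - 0.5)),
        int(np.ceil((center[1] + half - oy) / L - 0.5)),
        int(np.ceil((center[2] + half) / vz - 0.5)),
    ]
    lo = [max(0, v) for v in lo]
    hi = [min(n - 1, v) for v, n in zip(hi, (nx, ny, nz))]
    return lo, hi


def segment_ppv(
    segment: PathSegment,
    grid: VoxelGrid,
    v_swim: float,
) -> np.ndarray:
    """Flat indices of in-mask voxels inside one segment's ellipsoid.

    The speed budget is ``adjust_vswim(v_obs, v_swim) * dt`` (so segments
    observed at or above v_swim still produce a non-degenerate ellipsoid).
    The search scans only the ellipsoid's axis-aligned bounding box; the
    result is identical to a full-grid scan.
    """
    f1 = grid.to_real(segment.p1)
    f2 = grid.to_real(segment.p2)
    v = adjust_vswim(segment.v_obs, v_swim) if segment.v_obs >= v_swim else v_swim
    budget = v * segment.dt
    center = (f1 + f2) / 2.0
    half = budget / 2.0  # semi-major axis bounds the ellipsoid in every axis
    lo, hi = _candidate_box(grid, center, half)
    if any(l > h for l, h in zip(lo, hi)):
        return np.empty(0, dtype=np.int64)
    cx, cy, cz = grid.axis_centers_real()
    xs = cx[lo[0]:hi[0] + 1]
    ys = cy[lo[1]:hi[1] + 1]
    zs = cz[lo[2]:hi[2] + 1]
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    d1 = np.sqrt((gx - f1[0]) ** 2 + (gy - f1[1]) ** 2 + (gz - f1[2]) ** 2)
    d2 = np.sqrt((gx - f2[0]) ** 2 + (gy - f2[1]) ** 2 + (gz - f2[2]) ** 2)
    inside = (d1 + d2) <= budget
    inside &= grid.lake_mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    ix, iy, iz = np.nonzero(inside)
    return grid.flat(ix + lo[0], iy + lo[1], iz + lo[2]).astype(np.int64)


# ---------------------------------------------------------------------------
# Daily PPV and summaries
# ---------------------------------------------------------------------------

@dataclass
class DailyPPV:
    """Per-voxel segment-inclusion counts for one fish-day (sparse)."""

    fish_id: str
    date: _dt.date
    voxels: np.ndarray       # flat indices of voxels with count >= 1
    counts: np.ndarray       # same length; number of segment PPVs containing it
    n_segments: int
    v_swim_used: float
    dims: tuple[int, int, int]

    def mask_indices(self, threshold: int = 1) -> np.ndarray:
        """Flat indices of voxels with count >= threshold."""
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        return self.voxels[self.counts >= threshold]

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.dims, dtype=np.int64)
        out.ravel()[self.voxels] = self.counts
        return out


def daily_ppv(
    segments: Sequence[PathSegment],
    grid: VoxelGrid,
    v_swim: float,
) -> DailyPPV | None:
    """Sum segment PPVs of one fish-day into per-voxel inclusion counts.

    Returns None for an empty segment list (a gap-only fish-day yields no
    record rather than a zero volume).
    """
    if not segments:
        return None
    all_idx = [segment_ppv(seg, grid, v_swim) for seg in segments]
    stacked = np.concatenate(all_idx) if all_idx else np.empty(0, dtype=np.int64)
    voxels, counts = np.unique(stacked, return_counts=True)
    date = _dt.datetime.fromtimestamp(
        segments[0].p1.t, tz=_dt.timezone.utc).date()
    return DailyPPV(
        fish_id=segments[0].fish_id,
        date=date,
        voxels=voxels.astype(np.int64),
        counts=counts.astype(np.int64),
        n_segments=len(segments),
        v_swim_used=v_swim,
        dims=grid.dims,
    )


def habitat_volume(ppv: DailyPPV, grid: VoxelGrid, threshold: int = 1) -> float:
    """Voxel volume times the number of voxels used >= threshold times, m^3."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return float(len(ppv.mask_indices(threshold)) * grid.voxel_volume)


@dataclass
class RelativeUseSummary:
    """How concentrated one fish-day's use is across habitat voxels.

    ``denominator`` records whether fractions are over all in-mask lake
    voxels or only the voxels inside the day's bounding footprint (the
    axis-aligned envelope of the day's used voxels, intersected with the
    lake mask).
    """

    n_used_voxels: int
    n_denominator_voxels: int
    fraction_zero: float           # share of denominator voxels in no segment PPV
    fraction_ge5: float            # share included in >= 5 segment PPVs
    max_segment_fraction: float    # max over voxels of count / n_segments
    denominator: str               # "lake" or "footprint"


def relative_use_summary(
    ppv: DailyPPV,
    grid: VoxelGrid,
    denominator: str = "lake",
) -> RelativeUseSummary:
    """Relative-use fractions for one fish-day.

    With ``denominator="lake"`` fractions are over every in-mask habitat
    voxel of the study area; with ``"footprint"`` they are over the in-mask
    voxels inside the bounding box of the day's used voxels.
    """
    if ppv.n_segments < 1:
        raise ValueError("relative_use_summary needs n_segments >= 1")
    n_used = len(ppv.voxels)
    if denominator == "lake":
        n_denom = grid.n_lake_voxels
    elif denominator == "footprint":
        if n_used == 0:
            n_denom = 0
        else:
            ix, iy, iz = np.unravel_index(ppv.voxels, grid.dims)
            sub = grid.lake_mask[ix.min():ix.max() + 1,
                                 iy.min():iy.max() + 1,
                                 iz.min():iz.max() + 1]
            n_denom = int(sub.sum())
    else:
        raise ValueError("denominator must be 'lake' or 'footprint'")
    n_ge5 = int((ppv.counts >= 5).sum())
    return RelativeUseSummary(
        n_used_voxels=n_used,
        n_denominator_voxels=n_denom,
        fraction_zero=1.0 - n_used / n_denom if n_denom else 0.0,
        fraction_ge5=n_ge5 / n_denom if n_denom else 0.0,
        max_segment_fraction=(
            float(ppv.counts.max() / ppv.n_segments) if n_used else 0.0),
        denominator=denominator,
    )
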