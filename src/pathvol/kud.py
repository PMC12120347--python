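"""Kernel utilization distribution (KUD) habitat-volume estimators.

Two variants on the shared voxel lattice:

* 2D-KUD — a bivariate kernel density of the horizontal fixes; the
  highest-density cells accumulating 95% (by default) of the mass form the
  home-range region, and the fish is assumed to use the *entire water
  column* beneath it (volume = sum of cell area x lake depth).  This mimics
  having no depth sensor.
* 3D-KUD — a trivariate kernel density of (x, y, rescaled depth) evaluated
  at in-lake voxel centers and renormalized over the lake mask; the
  habitat volume is the voxel count of the 95% isopleth region times the
  voxel volume.

Densities are evaluated on voxel/cell centers so KUD regions and PPV counts
live on one comparable lattice, as the voxel-overlap definition requires.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

from .data_model import Bathymetry, Position
from .ppv import VoxelGrid

logger = logging.getLogger("pathvol")


@dataclass
class KudResult:
    fish_id: str
    date: _dt.date | None
    method: str                  # "kud2d" or "kud3d"
    mask: np.ndarray             # flat voxel indices inside the isopleth region
    volume: float                # m^3
    bandwidth: np.ndarray | None  # kernel covariance actually used
    bandwidth_rule: str          # e.g. "silverman"
    n_positions: int


def isopleth_mask(density: np.ndarray, level: float,
                  weights: np.ndarray | None = None) -> np.ndarray:
    """Highest-density region containing >= level of the total mass.

    Cells are sorted by density descending and accumulated until the
    cumulative mass reaches the level; all cells tied with the cutoff
    density are included, which makes the region deterministic and the
    masks nested across levels.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    mass = density * (weights if weights is not None else 1.0)
    total = mass.sum()
    if total <= 0:
        raise ValueError("total mass must be > 0")
    order = np.argsort(density)[::-1]
    cum = np.cumsum(mass[order]) / total
    n_core = int(np.searchsorted(cum, level * (1 - 1e-12)) + 1)
    n_core = min(n_core, len(density))
    cutoff = density[order[n_core - 1]]
    return density >= cutoff if cutoff > 0 else density > 0


def _kde(points: np.ndarray, bw_rule: str):
    """gaussian_kde with the named bandwidth rule; None on singular data."""
    try:
        return _sstats.gaussian_kde(points, bw_method=bw_rule)
    except np.linalg.LinAlgError:
        return None
    except ValueError:
        return None


def kud2d(
    positions: Sequence[Position],
    grid: VoxelGrid,
    bathymetry: Bathymetry,
    level: float = 0.95,
    bw_rule: str = "silverman",
    min_positions: int = 5,
) -> KudResult | None:
    """Full-water-column habitat volume from a bivariate (x, y) KUD.

    Density is evaluated at the horizontal centers of in-lake voxel columns;
    the isopleth region's volume is the sum of cell area x lake depth.  The
    3D mask is every in-mask voxel beneath a selected column.  Fish-days
    with fewer than ``min_positions`` fixes yield no record; singular
    position scatter (e.g. all fixes identical) falls back to the columns
    containing the fixes, with a warning.
    """
    if len(positions) < min_positions:
        logger.debug("kud2d: %d < %d positions, skipped", len(positions),
                     min_positions)
        return None
    cx, cy, _ = grid.axis_centers_rescaled()
    col_in_lake = grid.lake_mask.any(axis=2)  # (nx, ny)
    ii, jj = np.nonzero(col_in_lake)
    centers = np.stack([cx[ii], cy[jj]])  # (2, n_cols)
    pts = np.array([[p.x for p in positions], [p.y for p in positions]])
    kde = _kde(pts, bw_rule)
    if kde is None:
        logger.warning("kud2d: singular bandwidth; falling back to the cells "
                       "containing the fixes")
        sel = np.zeros(len(ii), dtype=bool)
        L = grid.voxel_length
        fix_i = np.floor((pts[0] - grid.origin[0]) / L).astype(int)
        fix_j = np.floor((pts[1] - grid.origin[1]) / L).astype(int)
        fix_cells = set(zip(fix_i, fix_j))
        for k, (i, j) in enumerate(zip(ii, jj)):
            if (i, j) in fix_cells:
                sel[k] = True
        bw = None
    else:
        density = kde(centers)
        if density.sum() <= 0:
            sel = np.zeros(len(ii), dtype=bool)
        else:
            sel = isopleth_mask(density, level)
        bw = kde.covariance
    lake_depth = bathymetry.depth_at(cx[ii[sel]], cy[jj[sel]])
    volume = float(np.nansum(lake_depth) * grid.voxel_length ** 2)
    mask3d = np.zeros(grid.dims, dtype=bool)
    mask3d[ii[sel], jj[sel], :] = True
    mask3d &= grid.lake_mask
    flat = np.flatnonzero(mask3d.ravel()).astype(np.int64)
    return KudResult(
        fish_id=positions[0].fish_id,
        date=None,
        method="kud2d",
        mask=flat,
        volume=volume,
        bandwidth=bw,
        bandwidth_rule=bw_rule,
        n_positions=len(positions),
    )


def kud3d(
    positions: Sequence[Position],
    grid: VoxelGrid,
    level: float = 0.95,
    bw_rule: str = "silverman",
    min_positions: int = 5,
    rescale_depth: bool = True,
    bbox_pad_sd: float = 5.0,
) -> KudResult | None:
    """Habitat volume from a trivariate KUD of (x, y, depth).

    Depth enters the kernel in the rescaled metric by default so the
    vertical kernel scale is commensurate with the horizontal one (set
    ``rescale_depth=False`` to fit on raw meters).  Density is evaluated at
    in-mask voxel centers within ``bbox_pad_sd`` marginal kernel SDs of the
    data (density outside is negligible and treated as zero), renormalized
    over the mask, and thresholded at the isopleth level.
    """
    if len(positions) < min_positions:
        return None
    zfac = grid.rescale if rescale_depth else 1.0
    pts = np.array([
        [p.x for p in positions],
        [p.y for p in positions],
        [p.depth * zfac for p in positions],
    ])
    kde = _kde(pts, bw_rule)
    cx, cy, cz = grid.axis_centers_rescaled()
    if not rescale_depth:
        cz = cz / grid.rescale
    if kde is None:
        logger.warning("kud3d: singular bandwidth; falling back to the voxels "
                       "containing the fixes")
        L = grid.voxel_length
        fi = np.floor((pts[0] - grid.origin[0]) / L).astype(int)
        fj = np.floor((pts[1] - grid.origin[1]) / L).astype(int)
        fk = np.floor(np.array([p.depth for p in positions])
                      * grid.rescale / L).astype(int)
        sel3d = np.zeros(grid.dims, dtype=bool)
        nx, ny, nz = grid.dims
        ok = (fi >= 0) & (fi < nx) & (fj >= 0) & (fj < ny) & (fk >= 0) & (fk < nz)
        sel3d[fi[ok], fj[ok], fk[ok]] = True
        sel3d &= grid.lake_mask
        flat = np.flatnonzero(sel3d.ravel()).astype(np.int64)
        return KudResult(positions[0].fish_id, None, "kud3d", flat,
                         float(len(flat) * grid.voxel_volume), None, bw_rule,
                         len(positions))
    sd = np.sqrt(np.diag(kde.covariance))
    lo = pts.min(axis=1) - bbox_pad_sd * sd
    hi = pts.max(axis=1) + bbox_pad_sd * sd
    sub = [
        np.flatnonzero((c >= l) & (c <= h))
        for c, l, h in zip((cx, cy, cz), lo, hi)
    ]
    if any(len(s) == 0 for s in sub):
        return None
    ix0, ix1 = sub[0][0], sub[0][-1]
    iy0, iy1 = sub[1][0], sub[1][-1]
    iz0, iz1 = sub[2][0], sub[2][-1]
    submask = grid.lake_mask[ix0:ix1 + 1, iy0:iy1 + 1, iz0:iz1 + 1]
    si, sj, sk = np.nonzero(submask)
    if len(si) == 0:
        return None
    eval_pts = np.stack([cx[si + ix0], cy[sj + iy0], cz[sk + iz0]])
    density = kde(eval_pts)
    if density.sum() <= 0:
        return None
    sel = isopleth_mask(density, level)
    flat = grid.flat(si[sel] + ix0, sj[sel] + iy0, sk[sel] + iz0).astype(np.int64)
    return KudResult(
        fish_id=positions[0].fish_id,
        date=None,
        method="kud3d",
        mask=np.sort(flat),
        volume=float(len(flat) * grid.voxel_volume),
        bandwidth=kde.covariance,
        bandwidth_rule=bw_rule,
        n_positions=len(positions),
    )
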