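"""Daily pairwise habitat overlap between fish, per estimation method.

Overlap between two fish on one day is the number of voxels shared by their
habitat masks times the voxel volume.  Masks are binary (for the PPV method,
voxels with inclusion count >= 1), so overlap is a volume of intersection,
never count-weighted.  A fish-day lacking a valid estimate contributes no
pair record (the pair is not evaluable, rather than a zero overlap).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .ppv import VoxelGrid

logger = logging.getLogger("pathvol")

METHODS = ("ppv", "kud2d", "kud3d")


@dataclass(frozen=True)
class OverlapRecord:
    date: _dt.date
    fish_a: str            # fish_a < fish_b by id
    fish_b: str
    method: str
    season: str | None
    overlap_volume: float  # m^3
    present: bool          # overlap_volume > 0


def overlap_volume(mask_a: np.ndarray, mask_b: np.ndarray,
                   grid: VoxelGrid) -> float:
    """Voxel volume times the number of voxels in both masks.

    Masks are flat voxel-index arrays on the *same* grid; indices beyond the
    grid size are a grid mismatch and fatal.
    """
    n_total = int(np.prod(grid.dims))
    for m in (mask_a, mask_b):
        if len(m) and (m.min() < 0 or m.max() >= n_total):
            raise ValueError("mask indices outside grid: grid mismatch")
    shared = np.intersect1d(mask_a, mask_b, assume_unique=False)
    return float(len(shared) * grid.voxel_volume)


def pair_table(
    daily_masks: Mapping[tuple[str, _dt.date, str], np.ndarray],
    grid: VoxelGrid,
    season_of: Mapping[_dt.date, str] | None = None,
) -> list[OverlapRecord]:
    """One record per (date, unordered fish pair, method) with both fish valid.

    ``daily_masks`` maps (fish_id, date, method) to a flat voxel-index mask.
    Pairs where either fish has no estimate for that date/method are omitted.
    """
    by_date_method: dict[tuple[_dt.date, str], list[str]] = {}
    for (fish, date, method) in daily_masks:
        by_date_method.setdefault((date, method), []).append(fish)
    records: list[OverlapRecord] = []
    for (date, method), fishes in sorted(by_date_method.items()):
        season = season_of.get(date) if season_of else None
        for fa, fb in combinations(sorted(set(fishes)), 2):
            vol = overlap_volume(
                daily_masks[(fa, date, method)],
                daily_masks[(fb, date, method)],
                grid,
            )
            records.append(OverlapRecord(
                date=date, fish_a=fa, fish_b=fb, method=method,
                season=season, overlap_volume=vol, present=vol > 0,
            ))
    return records


def overlap_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    """Columnar view (date, fish_a, fish_b, method, season, overlap_m3, present)."""
    return pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "fish_a": [r.fish_a for r in records],
            "fish_b": [r.fish_b for r in records],
            "method": [r.method for r in records],
            "season": [r.season for r in records],
            "overlap_m3": [r.overlap_volume for r in records],
            "present": [int(r.present) for r in records],
        }
    )
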