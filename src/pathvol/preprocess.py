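"""Position filtering, path segments, daily movement speeds, and seasons.

The filters mirror standard fine-scale acoustic-positioning QC for a lake
study: positions outside the shoreline, positions deeper than the local lake
depth plus a buffer (pressure-sensor or positioning artifacts), and positions
with a hyperbolic positioning error (HPE) above a cutoff are removed.
Consecutive retained fixes of one fish within one calendar day become path
segments; pairs separated by more than ``max_gap`` seconds are omitted and,
by construction, contribute zero volume to the daily potential path volume.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import Bathymetry, Position, TemperatureSeries

logger = logging.getLogger("pathvol")


@dataclass(frozen=True)
class PathSegment:
    """Two consecutive fixes of one fish plus elapsed time.

    ``v_obs`` is the straight-line 3D speed in real meters per second, the
    same metric in which the swim-speed parameter (a quantile of observed
    daily movement rates) is measured, so the degenerate-ellipsoid test
    compares like with like.
    """

    fish_id: str
    p1: Position
    p2: Position
    dt: float       # s, > 0
    v_obs: float    # m/s in rescaled space

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("segment dt must be > 0")


@dataclass
class SwimSpeedParam:
    """A swim-speed (v_swim) parameterization.

    Either one pooled scalar across all fish-days, or one value per
    (fish, season) group with the pooled value as fallback for groups
    without data.
    """

    quantile: float
    mode: str                      # "pooled" or "fish_season"
    pooled: float                  # m/s, always available
    by_group: dict | None = None   # {(fish_id, season): m/s}

    def value_for(self, fish_id: str, season: str | None = None) -> float:
        if self.mode == "pooled" or self.by_group is None:
            return self.pooled
        v = self.by_group.get((fish_id, season))
        if v is None:
            logger.debug("v_swim group (%s, %s) empty; pooled fallback",
                         fish_id, season)
            return self.pooled
        return v


@dataclass(frozen=True)
class DailySpeedRecord:
    fish_id: str
    date: _dt.date
    speed: float        # m/s, daily path length / elapsed time
    n_positions: int


# ---------------------------------------------------------------------------
# Daily binning
# ---------------------------------------------------------------------------

def day_of(t: float, offset: float = 0.0) -> _dt.date:
    """Calendar day of a UTC timestamp after applying the day-boundary offset."""
    return _dt.datetime.fromtimestamp(t + offset, tz=_dt.timezone.utc).date()


def group_by_fish_day(positions: Sequence[Position],
                      offset: float = 0.0) -> dict:
    """{(fish_id, date): time-sorted positions}."""
    out: dict[tuple[str, _dt.date], list[Position]] = {}
    for p in positions:
        out.setdefault((p.fish_id, day_of(p.t, offset)), []).append(p)
    for key in out:
        out[key].sort(key=lambda p: p.t)
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_positions(
    positions: Sequence[Position],
    bathymetry: Bathymetry,
    hpe_max: float = 20.0,
    depth_buffer: float = 2.0,
) -> tuple[list[Position], Counter]:
    """Apply the lake-mask, depth-buffer, and HPE filters.

    Each rejected position is tallied under the *first* failing reason, in the
    order outside_lake -> depth -> hpe (the order changes tallies only, never
    the kept set).  Positions falling in a no-data bathymetry cell count as
    ``outside_lake``.
    """
    kept: list[Position] = []
    tally: Counter = Counter()
    lake_depth = bathymetry.depth_at(
        np.array([p.x for p in positions], dtype=float),
        np.array([p.y for p in positions], dtype=float),
    ) if positions else np.empty(0)
    for p, ld in zip(positions, np.atleast_1d(lake_depth)):
        if not math.isfinite(ld):
            tally["outside_lake"] += 1
        elif p.depth > ld + depth_buffer:
            tally["depth"] += 1
        elif p.hpe > hpe_max:
            tally["hpe"] += 1
        else:
            kept.append(p)
    if sum(tally.values()):
        logger.info("filter_positions removed %d/%d (%s)",
                    sum(tally.values()), len(positions), dict(tally))
    return kept, tally


# ---------------------------------------------------------------------------
# Segments and daily speed
# ---------------------------------------------------------------------------

def _dedupe(positions: Sequence[Position]) -> list[Position]:
    """Drop positions sharing a timestamp with their predecessor (keep first)."""
    out: list[Position] = []
    dropped = 0
    for p in positions:
        if out and p.t == out[-1].t:
            dropped += 1
            continue
        out.append(p)
    if dropped:
        logger.debug("segmentize: dropped %d duplicate-timestamp fixes", dropped)
    return out


def segmentize(
    positions: Sequence[Position],
    max_gap: float = 1080.0,
) -> list[PathSegment]:
    """Consecutive-fix segments of one fish-day; gaps > max_gap omitted.

    Requires time-sorted positions of a single fish within one day bin.
    ``v_obs`` is the straight-line 3D speed in real meters per second.
    """
    pos = _dedupe(positions)
    if len(pos) < 2:
        return []
    segs: list[PathSegment] = []
    for p1, p2 in zip(pos[:-1], pos[1:]):
        dt = p2.t - p1.t
        if dt > max_gap:
            continue
        dist = math.sqrt(
            (p2.x - p1.x) ** 2
            + (p2.y - p1.y) ** 2
            + (p2.depth - p1.depth) ** 2
        )
        segs.append(PathSegment(fish_id=p1.fish_id, p1=p1, p2=p2,
                                dt=dt, v_obs=dist / dt))
    return segs


def daily_speed(positions: Sequence[Position]) -> DailySpeedRecord | None:
    """Total daily 3D path length / elapsed time between first and last fix.

    Distances here are in *unrescaled* meters (the vertical term is the raw
    depth difference); returns None below 2 usable positions.
    """
    pos = _dedupe(sorted(positions, key=lambda p: p.t))
    if len(pos) < 2:
        return None
    total = 0.0
    for p1, p2 in zip(pos[:-1], pos[1:]):
        total += math.sqrt(
            (p2.x - p1.x) ** 2 + (p2.y - p1.y) ** 2 + (p2.depth - p1.depth) ** 2
        )
    elapsed = pos[-1].t - pos[0].t
    return DailySpeedRecord(
        fish_id=pos[0].fish_id,
        date=day_of(pos[0].t),
        speed=total / elapsed,
        n_positions=len(pos),
    )


# ---------------------------------------------------------------------------
# v_swim selection and adjustment
# ---------------------------------------------------------------------------

def select_vswim(
    records: Iterable[DailySpeedRecord],
    quantile: float,
    mode: str = "pooled",
    season_of: Mapping[_dt.date, str] | None = None,
) -> SwimSpeedParam:
    """Quantile of the daily-speed distribution, pooled or per fish-season.

    Quantiles use the linear-interpolation empirical definition (numpy
    default).  In fish_season mode any empty group falls back to the pooled
    value at lookup time.
    """
    recs = list(records)
    if not recs:
        raise ValueError("select_vswim needs at least one daily speed record")
    speeds = np.array([r.speed for r in recs], dtype=float)
    pooled = float(np.quantile(speeds, quantile))
    if mode == "pooled":
        return SwimSpeedParam(quantile=quantile, mode=mode, pooled=pooled)
    if mode != "fish_season":
        raise ValueError(f"unknown v_swim mode {mode!r}")
    if season_of is None:
        raise ValueError("fish_season mode requires season labels")
    groups: dict[tuple[str, str], list[float]] = {}
    for r in recs:
        season = season_of.get(r.date)
        if season is None:
            continue
        groups.setdefault((r.fish_id, season), []).append(r.speed)
    by_group = {
        key: float(np.quantile(np.array(v), quantile)) for key, v in groups.items()
    }
    return SwimSpeedParam(quantile=quantile, mode=mode, pooled=pooled,
                          by_group=by_group)


def adjust_vswim(v_obs: float, v_swim: float) -> float:
    """Speed budget for one segment, handling the degenerate-ellipsoid case.

    When the observed speed meets or exceeds the swim-speed parameter the
    ellipsoid would collapse to the straight line between the fixes (volume
    0); the budget is then raised to ``1.01*v_obs + (v_obs - v_swim)``, which
    is strictly greater than v_obs.  Below the threshold v_swim is returned
    unchanged.
    """
    if v_obs <= 0 or v_swim <= 0:
        raise ValueError("adjust_vswim requires positive speeds")
    if v_obs < v_swim:
        return v_swim
    return 1.01 * v_obs + (v_obs - v_swim)


# ---------------------------------------------------------------------------
# Season delineation
# ---------------------------------------------------------------------------

def delineate_seasons(series: TemperatureSeries,
                      threshold: float = 15.0) -> dict[_dt.date, str]:
    """Label every date of the series with its season.

    winter = [ice_on, ice_off); spring = [ice_off, first day surface temp >
    threshold); summer = [that day, first subsequent day < threshold);
    fall = [that day, ice_on).  If the temperature never exceeds the
    threshold, spring extends to ice_on (no summer/fall) with a warning.
    """
    dates = series.dates
    temps = series.surface_temp
    summer_start = None
    fall_start = None
    for d, t in zip(dates, temps):
        if d < series.ice_off:
            continue
        if summer_start is None and t > threshold:
            summer_start = d
        elif summer_start is not None and fall_start is None and t < threshold:
            fall_start = d
    if summer_start is None:
        logger.warning("surface temperature never exceeded %.1f C: "
                       "no summer/fall delineated", threshold)
    labels: dict[_dt.date, str] = {}
    for d in dates:
        if d < series.ice_off or d >= series.ice_on:
            labels[d] = "winter"
        elif summer_start is None or d < summer_start:
            labels[d] = "spring"
        elif fall_start is None or d < fall_start:
            labels[d] = "summer"
        else:
            labels[d] = "fall"
    return labels
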