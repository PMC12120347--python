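"""End-to-end orchestration: simulate/load -> preprocess -> PPV -> KUD ->
overlap -> mixed models, with delimited-text outputs and a run manifest.

Every stage is also usable on its own through the library API; this module
just chains them on shared in-memory objects and writes the tables the CLI
exposes.  All randomness flows from one master seed, and tables are written
with fixed numeric formatting so identical runs are byte-identical.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (Bathymetry, Config, Position, TemperatureSeries,
                         write_bathymetry, write_positions, write_temperature)
from .kud import kud2d, kud3d
from .mixed_models import (MixedModelResult, fit_overlap_models,
                           fit_volume_method_season, fit_volume_npositions,
                           fit_volume_vswim, model_summary_frame)
from .overlap import overlap_frame, pair_table
from .ppv import build_voxel_grid, daily_ppv, habitat_volume
from .preprocess import (daily_speed, delineate_seasons, filter_positions,
                         group_by_fish_day, segmentize, select_vswim)
from .simulate import Scenario, default_scenario

logger = logging.getLogger("pathvol")

VSWIM_QUANTILES = (0.50, 0.75, 0.95, 1.00)
VSWIM_MODES = ("pooled", "fish_season")


def _qlabel(q: float) -> str:
    return f"Q{int(round(q * 100))}"


@dataclass
class PipelineResult:
    config: Config
    seed: int
    grid_summary: dict
    filter_tally: dict
    seasons: dict
    daily_speeds: pd.DataFrame
    vswim_table: pd.DataFrame
    volumes: pd.DataFrame          # fish_id, date, season, method, ..., volume_m3
    vswim_volumes: pd.DataFrame | None
    overlaps: pd.DataFrame
    stats: dict                    # name -> list[MixedModelResult]
    timings: dict


def run_pipeline(
    config: Config,
    positions: list[Position],
    bathymetry: Bathymetry,
    temperature: TemperatureSeries,
    seed: int = 0,
    compute_vswim_grid: bool = True,
    fit_stats: bool = True,
) -> PipelineResult:
    """Run every analysis stage on in-memory inputs."""
    timings: dict[str, float] = {}

    def _tick(stage, t_start):
        timings[stage] = round(time.perf_counter() - t_start, 3)

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    kept, tally = filter_positions(positions, bathymetry,
                                   hpe_max=config.hpe_max,
                                   depth_buffer=config.depth_buffer)
    seasons = delineate_seasons(temperature)
    by_day = group_by_fish_day(kept, offset=config.day_boundary_offset)
    speed_records = []
    for (fish, date), pos in sorted(by_day.items()):
        rec = daily_speed(pos)
        if rec is not None:
            speed_records.append(rec)
    if not speed_records:
        raise RuntimeError("preprocess produced no daily speed records")
    vswim_params = {
        (q, mode): select_vswim(speed_records, q, mode, seasons)
        for q in VSWIM_QUANTILES for mode in VSWIM_MODES
    }
    daily_speeds = pd.DataFrame({
        "fish_id": [r.fish_id for r in speed_records],
        "date": [r.date.isoformat() for r in speed_records],
        "speed_mps": [r.speed for r in speed_records],
        "n_positions": [r.n_positions for r in speed_records],
    })
    vswim_table = pd.DataFrame([
        {"quantile": _qlabel(q), "mode": mode,
         "fish_id": key[0] if key else "", "season": key[1] if key else "",
         "v_swim_mps": val}
        for (q, mode), param in sorted(vswim_params.items())
        for key, val in (
            sorted(param.by_group.items()) if param.mode == "fish_season"
            else [(None, param.pooled)]
        )
    ])
    _tick("preprocess", t0)

    # --- voxel grid and PPV ----------------------------------------------
    t0 = time.perf_counter()
    grid = build_voxel_grid(bathymetry, voxel_length=config.voxel_length,
                            rescale=config.rescale)
    segments_by_day = {
        key: segmentize(pos, max_gap=config.max_gap)
        for key, pos in sorted(by_day.items())
    }
    main_param = vswim_params[(config.vswim_quantile, config.vswim_mode)]
    volume_rows = []
    masks: dict[tuple, np.ndarray] = {}
    for (fish, date), segs in sorted(segments_by_day.items()):
        if not segs:
            continue
        season = seasons.get(date)
        vsw = main_param.value_for(fish, season)
        day = daily_ppv(segs, grid, vsw)
        if day is None:
            continue
        vol = habitat_volume(day, grid, threshold=config.volume_threshold)
        masks[(fish, date, "ppv")] = day.mask_indices(config.volume_threshold)
        volume_rows.append({
            "fish_id": fish, "date": date.isoformat(), "season": season,
            "method": "ppv", "n_positions": len(by_day[(fish, date)]),
            "n_segments": day.n_segments, "v_swim": vsw, "volume_m3": vol,
        })
    _tick("ppv", t0)

    # --- KUD --------------------------------------------------------------
    t0 = time.perf_counter()
    for (fish, date), pos in sorted(by_day.items()):
        season = seasons.get(date)
        common = dict(level=config.isopleth_level, bw_rule=config.kud_bandwidth,
                      min_positions=config.min_kud_positions)
        r2d = kud2d(pos, grid, bathymetry, **common)
        r3d = kud3d(pos, grid, **common)
        for res in (r2d, r3d):
            if res is None or res.volume <= 0:
                continue
            masks[(fish, date, res.method)] = res.mask
            volume_rows.append({
                "fish_id": fish, "date": date.isoformat(), "season": season,
                "method": res.method, "n_positions": res.n_positions,
                "n_segments": 0, "v_swim": np.nan, "volume_m3": res.volume,
            })
    volumes = pd.DataFrame(volume_rows).sort_values(
        ["method", "fish_id", "date"]).reset_index(drop=True)
    _tick("kud", t0)

    # --- v_swim sensitivity grid -----------------------------------------
    vswim_volumes = None
    if compute_vswim_grid:
        t0 = time.perf_counter()
        rows = []
        for (q, mode), param in sorted(vswim_params.items()):
            for (fish, date), segs in sorted(segments_by_day.items()):
                if not segs:
                    continue
                season = seasons.get(date)
                vsw = param.value_for(fish, season)
                day = daily_ppv(segs, grid, vsw)
                if day is None:
                    continue
                rows.append({
                    "fish_id": fish, "date": date.isoformat(),
                    "season": season,
                    "vswim_quantile": _qlabel(q), "vswim_mode": mode,
                    "v_swim": vsw,
                    "volume_m3": habitat_volume(
                        day, grid, threshold=config.volume_threshold),
                })
        vswim_volumes = pd.DataFrame(rows)
        _tick("vswim_grid", t0)

    # --- overlap ----------------------------------------------------------
    t0 = time.perf_counter()
    records = pair_table(masks, grid, season_of=seasons)
    overlaps = overlap_frame(records)
    _tick("overlap", t0)

    # --- mixed models -----------------------------------------------------
    stats: dict[str, list[MixedModelResult]] = {}
    if fit_stats:
        t0 = time.perf_counter()
        ppv_only = volumes[volumes["method"] == "ppv"]
        if ppv_only["fish_id"].nunique() >= 2 and len(ppv_only) >= 10:
            stats["npositions"] = fit_volume_npositions(ppv_only)
            stats["method_season"] = fit_volume_method_season(volumes)
            if vswim_volumes is not None and len(vswim_volumes):
                stats["vswim"] = fit_volume_vswim(vswim_volumes)
            if len(overlaps) and overlaps["present"].nunique() > 1:
                try:
                    both = fit_overlap_models(overlaps)
                    stats["overlap_presence"] = both["presence"]
                    stats["overlap_magnitude"] = both["magnitude"]
                except ValueError as exc:
                    logger.warning("overlap models skipped: %s", exc)
        else:
            logger.warning("too few fish/days for mixed models; stats skipped")
        _tick("stats", t0)

    return PipelineResult(
        config=config,
        seed=seed,
        grid_summary={
            "dims": list(grid.dims),
            "voxel_volume_m3": grid.voxel_volume,
            "n_lake_voxels": grid.n_lake_voxels,
            "masked_volume_m3": grid.masked_volume,
            "lake_volume_m3": bathymetry.lake_volume,
        },
        filter_tally=dict(tally),
        seasons={d.isoformat(): s for d, s in sorted(seasons.items())},
        daily_speeds=daily_speeds,
        vswim_table=vswim_table,
        volumes=volumes,
        vswim_volumes=vswim_volumes,
        overlaps=overlaps,
        stats=stats,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(result: PipelineResult, outdir: str | Path,
                  inputs: dict[str, Path] | None = None) -> Path:
    """Write all stage tables plus a reproducibility manifest; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_csv(result.daily_speeds, outdir / "daily_speeds.csv")
    _write_csv(result.vswim_table, outdir / "vswim.csv")
    _write_csv(result.volumes, outdir / "volumes.csv")
    if result.vswim_volumes is not None:
        _write_csv(result.vswim_volumes, outdir / "vswim_volumes.csv")
    _write_csv(result.overlaps, outdir / "overlaps.csv")
    pd.DataFrame(
        {"date": list(result.seasons), "season": list(result.seasons.values())}
    ).to_csv(outdir / "seasons.csv", index=False)
    for name, models in result.stats.items():
        _write_csv(model_summary_frame(models), outdir / f"stats_{name}.csv")
        _write_csv(models[0].coef_frame(), outdir / f"stats_{name}_coefs.csv")
    manifest = {
        "version": __version__,
        "seed": result.seed,
        "config": {k: v for k, v in vars(result.config).items()},
        "grid": result.grid_summary,
        "filter_tally": result.filter_tally,
        "timings_s": result.timings,
        "inputs": {k: _sha256(Path(v)) for k, v in (inputs or {}).items()},
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def run_all(
    config: Config,
    outdir: str | Path,
    seed: int = 0,
    scenario: Scenario | None = None,
    n_fish: int = 9,
    days: int = 60,
    lake_shape: str = "paraboloid",
    compute_vswim_grid: bool = True,
    fit_stats: bool = True,
    write_inputs: bool = True,
) -> PipelineResult:
    """Simulate (unless a scenario is supplied) and run the full pipeline,
    writing every stage output plus input files and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scenario is None:
        scenario = default_scenario(seed=seed, n_fish=n_fish, days=days,
                                    lake_shape=lake_shape)
    inputs = {}
    if write_inputs:
        write_positions(scenario.positions, outdir / "positions.csv")
        write_bathymetry(scenario.lake, outdir / "bathymetry.asc")
        write_temperature(scenario.temperature, outdir / "temperature.csv")
        inputs = {
            "positions": outdir / "positions.csv",
            "bathymetry": outdir / "bathymetry.asc",
            "temperature": outdir / "temperature.csv",
        }
    result = run_pipeline(
        config,
        scenario.positions,
        scenario.lake,
        scenario.temperature,
        seed=seed,
        compute_vswim_grid=compute_vswim_grid,
        fit_stats=fit_stats,
    )
    write_outputs(result, outdir, inputs=inputs)
    return result
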