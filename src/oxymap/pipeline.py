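"""Stage-wise pipeline driver: design -> simulate -> fit -> sobol ->
maps -> report, each stage exchanging NetCDF files in one output
directory and appending to a JSON run manifest.

The stages are plain functions so they can be called from Python; the
command-line interface in :mod:`oxymap.cli` is a thin wrapper.  A run
is fully determined by (config, seed): the quadrature design and the
column solver are deterministic, and the single seed governs world
generation only, so re-running a stage reproduces its output files
byte for byte (the manifest, which carries wall-clock timestamps, is
the only exception).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import xarray as xr

from . import __version__
from .archive import (
    NETCDF_ENGINE,
    EnsembleArchive,
    dataset_to_pce,
    dataset_to_sobol,
    pce_to_dataset,
    read_archive,
    sobol_to_dataset,
)
from .config import PipelineConfig, config_hash
from .diagnostics import (
    benchmark_report,
    benchmark_scores,
    compute_diagnostics,
    regional_average,
)
from .pce import fit_pce, sobol_decompose
from .toyocean import TIME_SLICES, generate_world, run_ensemble

__all__ = [
    "stage_design",
    "stage_simulate",
    "stage_fit",
    "stage_sobol",
    "stage_maps",
    "stage_report",
    "run_all",
    "FIELD_NAMES",
]

log = logging.getLogger(__name__)

#: Output fields carried through fit/sobol: the three time slices plus
#: the preindustrial-to-projected change.
FIELD_NAMES = ("min_O2_1850", "min_O2_2000", "min_O2_2100", "delta_min_O2_1850_2100")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _update_manifest(outdir: Path, stage: str, cfg: PipelineConfig, seed: int, inputs: list[Path], outputs: list[Path]) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": []}
    manifest["config_hash"] = config_hash(cfg)
    manifest["seed"] = seed
    manifest["version"] = __version__
    manifest["stages"] = [s for s in manifest["stages"] if s["stage"] != stage]
    manifest["stages"].append(
        {
            "stage": stage,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "inputs": {p.name: _sha256(p) for p in inputs},
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    )
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing {path.name}: run the '{producer}' stage first")
    return path


def _log_settings(cfg: PipelineConfig) -> None:
    p = cfg.parameters
    log.info(
        "settings: rel_sd w=%g kappa=%g a=%g, points_per_dim=%d, max_order=%d, mask_threshold=%g",
        p.w.rel_sd, p.kappa.rel_sd, p.a.rel_sd,
        cfg.quadrature.points_per_dim, cfg.quadrature.max_order,
        cfg.diagnostics.mask_threshold,
    )


def stage_design(cfg: PipelineConfig, outdir: Path, seed: int) -> Path:
    """Write the quadrature design (nodes and weights) to design.nc."""
    from .pce import build_design

    outdir.mkdir(parents=True, exist_ok=True)
    _log_settings(cfg)
    design = build_design(cfg.parameter_set(), cfg.quadrature.points_per_dim)
    ds = xr.Dataset(
        {
            "node_phys": (("run", "param"), design.nodes_phys),
            "node_std": (("run", "param"), design.nodes_std),
            "weight": (("run",), design.weights),
        },
        coords={
            "run": ("run", np.arange(design.n_runs, dtype=np.int32)),
            "param": ("param", np.arange(3, dtype=np.int32)),
        },
        attrs={"param_names": "w kappa a", "points_per_dim": np.int32(design.points_per_dim)},
    )
    out = outdir / "design.nc"
    ds.to_netcdf(out, engine=NETCDF_ENGINE)
    _update_manifest(outdir, "design", cfg, seed, [], [out])
    log.info("design: %d runs -> %s", design.n_runs, out)
    return out


def stage_simulate(cfg: PipelineConfig, outdir: Path, seed: int) -> Path:
    """Run the synthetic ensemble and write archive.nc."""
    from .pce import build_design

    outdir.mkdir(parents=True, exist_ok=True)
    _log_settings(cfg)
    design = build_design(cfg.parameter_set(), cfg.quadrature.points_per_dim)
    world = generate_world(cfg.world_config(), seed)
    archive = run_ensemble(design, world, cfg.grid(), cfg.constants(), TIME_SLICES, progress=True)
    archive.ds.attrs["seed"] = np.int32(seed)
    archive.ds.attrs["config_hash"] = config_hash(cfg)
    out = outdir / "archive.nc"
    archive.to_netcdf(out)
    _update_manifest(outdir, "simulate", cfg, seed, [], [out])
    log.info("simulate: %d runs x %d columns x %d slices -> %s",
             archive.n_runs, archive.n_columns, len(archive.times), out)
    return out


def stage_fit(cfg: PipelineConfig, outdir: Path, seed: int, archive_path: Path | None = None) -> Path:
    """Fit per-column PCEs for each time slice and the change field."""
    _log_settings(cfg)
    apath = archive_path or _require(outdir / "archive.nc", "simulate")
    archive = read_archive(apath)
    design = archive.design
    fields = {}
    for year in archive.times:
        fields[f"min_O2_{year}"] = fit_pce(
            design, archive.slice(year).values, cfg.quadrature.max_order, f"min_O2_{year}"
        )
    if 1850 in archive.times and 2100 in archive.times:
        delta = (archive.slice(2100) - archive.slice(1850)).values
        fields["delta_min_O2_1850_2100"] = fit_pce(
            design, delta, cfg.quadrature.max_order, "delta_min_O2_1850_2100"
        )
    out = outdir / "pce.nc"
    pce_to_dataset(fields).to_netcdf(out, engine=NETCDF_ENGINE)
    _update_manifest(outdir, "fit", cfg, seed, [apath], [out])
    log.info("fit: %d fields x %d terms -> %s", len(fields), len(next(iter(fields.values())).basis), out)
    return out


def stage_sobol(cfg: PipelineConfig, outdir: Path, seed: int) -> Path:
    """Sobol decomposition of every fitted field."""
    ppath = _require(outdir / "pce.nc", "fit")
    with xr.open_dataset(ppath, engine=NETCDF_ENGINE) as ds:
        pces = dataset_to_pce(ds.load())
    sobols = {name: sobol_decompose(pce) for name, pce in pces.items()}
    out = outdir / "sobol.nc"
    sobol_to_dataset(sobols).to_netcdf(out, engine=NETCDF_ENGINE)
    _update_manifest(outdir, "sobol", cfg, seed, [ppath], [out])
    log.info("sobol: %d fields -> %s", len(sobols), out)
    return out


def stage_maps(cfg: PipelineConfig, outdir: Path, seed: int, weighted: bool | None = None) -> Path:
    """Diagnostic maps: mean change, noise-to-signal, spread, CV, mask."""
    apath = _require(outdir / "archive.nc", "simulate")
    spath = _require(outdir / "sobol.nc", "sobol")
    archive = read_archive(apath)
    with xr.open_dataset(spath, engine=NETCDF_ENGINE) as ds:
        sobols = dataset_to_sobol(ds.load())
    if weighted is None:
        weighted = cfg.diagnostics.weighted
    maps = compute_diagnostics(
        archive,
        sobols["min_O2_2000"],
        weighted=weighted,
        eps=cfg.diagnostics.eps,
        mask_threshold=cfg.diagnostics.mask_threshold,
    )
    N = archive.n_columns
    ds = xr.Dataset(
        {
            "mean_change": (("column",), maps.mean_change, {"units": "mmol m-3"}),
            "noise_to_signal": (("column",), maps.noise_to_signal, {"units": "%"}),
            "contemporary_spread": (("column",), maps.contemporary_spread, {"units": "mmol m-3"}),
            "contemporary_cv": (("column",), maps.contemporary_cv, {"units": "%"}),
            "low_variance_mask": (("column",), maps.low_variance_mask.astype(np.int8)),
        },
        coords={"column": ("column", np.arange(N, dtype=np.int32))},
        attrs={
            "rank_correlation_cv_vs_ns": float(maps.rank_correlation),
            "weighted": np.int32(bool(weighted)),
        },
    )
    out = outdir / "maps.nc"
    ds.to_netcdf(out, engine=NETCDF_ENGINE)
    _update_manifest(outdir, "maps", cfg, seed, [apath, spath], [out])
    log.info("maps: rank correlation (contemporary CV vs projected N/S) = %.3f -> %s",
             maps.rank_correlation, out)
    return out


def stage_report(cfg: PipelineConfig, outdir: Path, seed: int, weighted: bool | None = None) -> list[Path]:
    """Regional Sobol table and benchmarking-region listing."""
    apath = _require(outdir / "archive.nc", "simulate")
    spath = _require(outdir / "sobol.nc", "sobol")
    mpath = _require(outdir / "maps.nc", "maps")
    archive = read_archive(apath)
    with xr.open_dataset(spath, engine=NETCDF_ENGINE) as ds:
        sobols = dataset_to_sobol(ds.load())
    with xr.open_dataset(mpath, engine=NETCDF_ENGINE) as ds:
        maps_ds = ds.load()
    mask = maps_ds["low_variance_mask"].values.astype(bool)
    spread = maps_ds["contemporary_spread"].values

    regions = cfg.region_masks()
    table = regional_average(sobols["delta_min_O2_1850_2100"], regions, archive, mask)
    table_path = outdir / "regional_sobol.tsv"
    table.to_csv(table_path, sep="\t", float_format="%.3f")

    scores = benchmark_scores(sobols["min_O2_2000"], spread, mask, cfg.diagnostics.spread_quantile)
    bench = benchmark_report(scores, archive, cfg.diagnostics.top_k)
    bench_path = outdir / "benchmark_regions.tsv"
    bench.to_csv(bench_path, sep="\t", index=False, float_format="%.3f")

    _update_manifest(outdir, "report", cfg, seed, [apath, spath, mpath], [table_path, bench_path])
    log.info("report: regional Sobol table -> %s; benchmark regions -> %s", table_path, bench_path)
    return [table_path, bench_path]


def run_all(cfg: PipelineConfig, outdir: Path, seed: int, weighted: bool | None = None) -> list[Path]:
    """Chain every stage in order; returns all output paths."""
    outdir = Path(outdir)
    outputs = [stage_design(cfg, outdir, seed), stage_simulate(cfg, outdir, seed)]
    outputs.append(stage_fit(cfg, outdir, seed))
    outputs.append(stage_sobol(cfg, outdir, seed))
    outputs.append(stage_maps(cfg, outdir, seed, weighted))
    outputs.extend(stage_report(cfg, outdir, seed, weighted))
    return outputs
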