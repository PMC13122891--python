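"""End-to-end orchestration: simulate or load, call, summarize, report.

``run_pipeline`` takes a config mapping (usually loaded from YAML),
executes normalize -> stats -> flag -> runs -> call -> merge ->
summarize (plus the array screen when a genotype matrix is present or
simulated), writes BED/TSV outputs and a machine-readable run log under
a run directory, and returns the result bundle in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import axiom as ax
from . import caller, depth, io, simulate
from .runs import DEFAULT_ALPHA_LEVELS
from .saturation import SaturationModel

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {self.label!r} failed: {exc}") from exc
            return False

    return _Ctx(name)


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the full analysis described by ``config``.

    The config either names input files (``inputs.depth_tracks``,
    ``inputs.genotype_matrix``) or a simulation spec (``simulate``);
    ``seed`` overrides ``config['seed']``.  All outputs land under
    ``out_dir`` with a manifest; the pipeline is deterministic given
    config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    gcfg = config.get("genome", {})
    ccfg = config.get("calling", {})
    acfg = config.get("axiom", {})
    scfg = config.get("saturation", {})
    alpha_levels = tuple(ccfg.get("alpha_levels", DEFAULT_ALPHA_LEVELS))

    manifest: dict = {"seed": seed, "outputs": []}
    bundle: dict = {}

    def write(name, fn):
        path = out / name
        fn(path)
        manifest["outputs"].append(name)
        return path

    truth = None
    with _stage("input"):
        if "simulate" in config:
            sim = dict(config["simulate"])
            grid = simulate.make_genome(
                gcfg["chromosomes"],
                window_size=int(gcfg.get("window_size", 10_000)),
                mappability_sd=float(gcfg.get("mappability_sd", 0.0)),
                seed=seed,
            )
            sc = simulate.SimConfig(
                n_lines=int(sim.get("n_lines", 20)),
                mean_reads_per_window=float(sim.get("mean_reads_per_window", 67.0)),
                marker_count=int(sim.get("marker_count", 71_562)),
                null_error_rate=float(sim.get("null_error_rate", 0.001)),
                het_error_rate=float(sim.get("het_error_rate", 0.03)),
                seed=seed,
            )
            truth = simulate.implant_events(
                grid,
                n_lines=sc.n_lines,
                events_per_line=int(sim.get("events_per_line", 5)),
                min_size=int(sim.get("min_size", 30_000)),
                max_size=int(sim.get("max_size", 3_000_000)),
                zygosity_mix=sim.get("zygosity_mix"),
                seed=seed,
            )
            raw = simulate.simulate_depth(grid, truth, sc)
            marker_matrix, marker_ledger = (
                simulate.simulate_marker_calls(grid, truth, sc)
                if sim.get("markers", True)
                else (None, None)
            )
            write("truth.bed", truth.to_bed)
        elif "inputs" in config:
            grid = simulate.make_genome(
                gcfg["chromosomes"], window_size=int(gcfg.get("window_size", 10_000))
            )
            raw = depth.read_window_counts(config["inputs"]["depth_tracks"], grid)
            gm = config["inputs"].get("genotype_matrix")
            marker_matrix = ax.read_genotype_matrix(gm) if gm else None
            marker_ledger = None
        else:
            raise ValueError("config needs either a 'simulate' or an 'inputs' section")

    with _stage("normalize"):
        norm = depth.normalize(raw)
    with _stage("stats"):
        stats = depth.window_stats(norm, min_mu=float(ccfg.get("min_mu", 0.1)))
        write("window_stats.tsv", lambda p: stats.to_frame().to_csv(p, sep="\t", index=False))

    with _stage("call"):
        calls, fitted = caller.call_population(
            norm,
            stats,
            gap_tolerance=int(ccfg.get("gap_tolerance", 1)),
            alpha_levels=alpha_levels,
            merge_gap_bp=int(ccfg.get("merge_gap_bp", 200_000)),
        )
        write("cnv_calls.bed", lambda p: io.calls_to_bed(calls, p))
        write(
            "cnv_calls.tsv",
            lambda p: io.calls_to_frame(calls).to_csv(p, sep="\t", index=False),
        )

    axiom_calls = []
    with _stage("axiom"):
        if marker_matrix is not None:
            filtered, removed = ax.filter_fixed_heterozygotes(marker_matrix)
            for line in filtered.line_ids:
                line_calls, _ = ax.null_runs(
                    filtered,
                    line,
                    min_run=int(acfg.get("min_run", 3)),
                    interruption_tolerance=int(acfg.get("interruption_tolerance", 1)),
                    alpha_levels=alpha_levels,
                    merge_gap_markers=int(acfg.get("merge_gap_markers", 5)),
                )
                axiom_calls.extend(ax.classify_interruptions(filtered, c) for c in line_calls)
            write(
                "axiom_calls.tsv",
                lambda p: io.axiom_calls_to_frame(axiom_calls).to_csv(p, sep="\t", index=False),
            )

    with _stage("summarize"):
        spectrum = caller.unique_deletions(
            calls,
            genome_bp=grid.total_bp,
            reciprocal_overlap=float(ccfg.get("reciprocal_overlap", 0.5)),
            bin_bp=grid.window_size,
        )
        dup_summary = caller.duplication_spacing(calls)
        write(
            "size_spectrum.tsv",
            lambda p: spectrum.to_frame().to_csv(p, sep="\t", index=False),
        )
        sat = SaturationModel(
            deleted_bp=spectrum.unique_deleted_bp,
            genome_bp=float(scfg.get("genome_bp", grid.total_bp)),
            n_families=len(norm.line_ids),
            M=int(scfg.get("population_families", 5000)),
        )

        summary = {
            "n_lines": len(norm.line_ids),
            "n_windows": grid.n_windows,
            "n_unmasked_windows": stats.n_unmasked,
            "n_calls": len(calls),
            "n_axiom_calls": len(axiom_calls),
            "n_unique_deletions": spectrum.n_unique,
            "unique_deleted_bp": spectrum.unique_deleted_bp,
            "genome_fraction_deleted": spectrum.genome_fraction,
            "duplication_spacing": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in dup_summary.items()
            },
            "saturation": sat.report(),
            "p_estimates": {
                f"{line}:{mode}": params.p for (line, mode), params in fitted.items()
            },
            "alpha_levels": list(alpha_levels),
            "seed": seed,
        }
        write(
            "summary.json",
            lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)),
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    bundle.update(
        grid=grid,
        truth=truth,
        depth=norm,
        stats=stats,
        calls=calls,
        fitted_params=fitted,
        axiom_calls=axiom_calls,
        spectrum=spectrum,
        summary=summary,
    )
    return bundle
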