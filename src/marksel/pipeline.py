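"""End-to-end run configuration and orchestration.

``run_pipeline`` wires the full workflow on one configuration: load (or
generate) a candidate-father panel, apply the dataset-construction filters,
build the power tensor and adjacency weights, optimize a marker set, and
optionally simulate offspring and score exclusion-based assignment. Every
artifact lands in the output directory together with a resolved copy of the
configuration and a run manifest (versions, seeds, timings).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .assign import assign_paternity, score_assignments
from .genotype_io import (
    export_cervus,
    filter_maf,
    load_marker_map,
    load_panel,
    prune_spacing_ld,
    write_dosage_tsv,
    write_offspring_tsv,
    write_solution,
)
from .heuristics import METHODS, optimize
from .simulate import (
    SyntheticPanelSpec,
    generate_panel,
    mask_genotypes,
    simulate_study_offspring,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated inputs for one pipeline run.

    Either ``genotype_path`` (+ format + maternal id) or ``synthetic`` must
    be set; ``synthetic`` holds SyntheticPanelSpec keyword arguments.
    """

    out_dir: str = "marksel_run"
    genotype_path: str | None = None
    format: str = "dosage-tsv"
    maternal_id: str | None = None
    map_path: str | None = None
    lengths_path: str | None = None
    synthetic: dict | None = None
    # filters
    maf_min: float = 0.05
    window: int = 50
    r2_max: float = 0.5
    min_bp: int = 10_000
    apply_prune: bool = True
    # optimization
    h: float = 8.0
    method: str = "greedy+ns"
    v: float = 0.2
    time_limit: float = 3600.0
    max_rounds: int = 50
    # evaluation
    simulate_offspring: bool = True
    n_per_father: int = 5
    masking_rate: float = 0.0
    max_mismatch: int = 0
    seed: int = 0
    cervus_export: bool = False

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.synthetic is None:
            if self.genotype_path is None or self.maternal_id is None:
                raise ValueError("need genotype_path and maternal_id (or synthetic spec)")
            if self.method != "ilp-count" and self.map_path is None:
                raise ValueError(f"method {self.method!r} needs a marker map")
            if self.map_path is not None and self.lengths_path is None:
                raise ValueError("marker map given without chromosome lengths")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min out of range")
        if not 0 <= self.v <= 1:
            raise ValueError("flip fraction v out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    manifest: dict = {"version": __version__, "stages": {}, "seed": config.seed}
    stage = "setup"
    try:
        t0 = time.perf_counter()
        stage = "load"
        if config.synthetic is not None:
            spec = SyntheticPanelSpec(**{**config.synthetic, "seed": config.seed})
            panel, mmap = generate_panel(spec)
        else:
            panel = load_panel(config.genotype_path, config.format, config.maternal_id)
            mmap = (
                load_marker_map(config.map_path, config.lengths_path)
                if config.map_path
                else None
            )
        manifest["stages"]["load"] = {
            "n_individuals": panel.n_individuals,
            "n_markers": panel.n_markers,
            "time": time.perf_counter() - t0,
        }

        stage = "filter"
        t0 = time.perf_counter()
        panel = filter_maf(panel, config.maf_min)
        if config.apply_prune and mmap is not None:
            panel = prune_spacing_ld(
                panel, mmap, window=config.window, r2_max=config.r2_max, min_bp=config.min_bp
            )
        write_dosage_tsv(panel, out / "filtered_panel.tsv", include_mother=True)
        manifest["stages"]["filter"] = {
            "n_markers": panel.n_markers,
            "time": time.perf_counter() - t0,
        }

        stage = "optimize"
        t0 = time.perf_counter()
        solution, report = optimize(
            panel,
            mmap,
            h=config.h,
            method=config.method,
            v=config.v,
            time_limit=config.time_limit,
            max_rounds=config.max_rounds,
        )
        if solution is None:
            raise RuntimeError(
                f"optimization infeasible; weakest pairs: {report.infeasible_pairs[:5]}"
            )
        write_solution(
            solution, mmap, out / "solution.tsv", out / "solution_metrics.json",
            status=report.status,
        )
        manifest["stages"]["optimize"] = {
            "method": config.method,
            "status": report.status,
            "f": solution.f,
            "g": solution.g,
            "depth": solution.depth,
            "dropped_pairs": len(report.infeasible_pairs or []),
            "time": time.perf_counter() - t0,
        }

        if config.simulate_offspring:
            stage = "simulate"
            t0 = time.perf_counter()
            offspring = simulate_study_offspring(
                panel, n_per_father=config.n_per_father, seed=config.seed + 1
            )
            if config.masking_rate > 0:
                offspring = mask_genotypes(offspring, config.masking_rate, seed=config.seed + 2)
            write_offspring_tsv(
                offspring, out / "offspring.tsv", out / "offspring_truth.tsv"
            )
            manifest["stages"]["simulate"] = {
                "n_offspring": offspring.n_offspring,
                "masking_rate": offspring.masking_rate,
                "time": time.perf_counter() - t0,
            }

            stage = "assign"
            t0 = time.perf_counter()
            result = assign_paternity(
                offspring, panel, solution, max_mismatch=config.max_mismatch
            )
            summary = score_assignments(result)
            result.table.to_csv(out / "assignments.tsv", sep="\t", index=False)
            (out / "assignment_summary.json").write_text(
                json.dumps(summary, indent=2) + "\n"
            )
            manifest["stages"]["assign"] = {**summary, "time": time.perf_counter() - t0}

            if config.cervus_export:
                stage = "export-cervus"
                export_cervus(panel, offspring, solution, out / "cervus")

        manifest["status"] = "ok"
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
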