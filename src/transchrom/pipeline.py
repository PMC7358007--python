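"""Pipeline orchestration: simulate -> deletions -> dosage -> retention -> behavior.

A single human-editable YAML config drives the run; every stage reads
the previous stage's plain-text outputs, so any stage can also be run
in isolation from the CLI. All randomness flows from the one ``seed``
field. Identical config + seed produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import behavior as beh
from . import dosage as dos
from . import genome as gen
from . import io as tio
from . import retention as ret
from .simulate import (
    SimulationConfig,
    generate_annotation,
    generate_cell_observations,
    generate_depth_profile,
    generate_expression_counts,
    generate_probe_trials,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate_inputs"]

log = logging.getLogger("transchrom")


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, stage parameters, and the global seed for one run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    # input paths (filled by the simulate stage, or supplied for real data)
    annotation: str | None = None
    depth: str | None = None
    counts_eu: str | None = None
    counts_tc: str | None = None
    library_sizes: str | None = None
    cells: str | None = None
    trials: str | None = None
    truth: str | None = None
    # deletion caller
    deletion_threshold: float = 0.25
    deletion_min_bins: int = 3
    deletion_merge_gap_bins: int = 1
    # dosage
    min_fpkm: float = 1.0
    dysregulation_low: float = 0.8
    dysregulation_high: float = 1.2
    # retention
    retention_conf: float = 0.95
    mosaic_threshold: float = 0.9
    # behavior (probe-trial generation when simulating)
    n_animals: int = 9
    baseline_fraction: float = 0.30
    retention_decay_per_day: float = 0.85
    # simulator overrides (field name -> value of SimulationConfig)
    sim_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.deletion_threshold <= 0 or self.min_fpkm <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        overrides = dict(self.sim_overrides)
        overrides["seed"] = self.seed
        if "planted_deletions" in overrides:
            overrides["planted_deletions"] = tuple(
                tuple(iv) for iv in overrides["planted_deletions"]
            )
        if "tissues" in overrides:
            overrides["tissues"] = tuple(overrides["tissues"])
        return SimulationConfig(**overrides)


def _require(path: str | None, what: str, stage: str) -> Path:
    if path is None:
        raise PipelineError(stage, f"no {what} file configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"{what} file not found: {p}")
    return p


def simulate_inputs(config: PipelineConfig) -> PipelineConfig:
    """Generate all pipeline inputs into ``out_dir/inputs`` and return a
    config pointing at them."""
    out = Path(config.out_dir) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()
    log.info("simulate: seed=%d span=%d bp", sim.seed, sim.span_bp)

    annotation, truth = generate_annotation(sim)
    profile = generate_depth_profile(sim, truth)
    eu, tc, libs = generate_expression_counts(sim, annotation, truth)
    cells = generate_cell_observations(sim, truth)
    trials = generate_probe_trials(
        config.n_animals,
        config.baseline_fraction,
        config.retention_decay_per_day,
        seed=sim.seed,
    )

    tio.write_annotation(annotation, out / "annotation.tsv")
    tio.write_annotation_bed6(annotation, out / "annotation.bed")
    tio.write_bedgraph(profile, out / "depth.bedgraph")
    tio.write_counts(eu, out / "counts_eu.tsv")
    tio.write_counts(tc, out / "counts_tc.tsv")
    tio.write_library_sizes(libs, out / "library_sizes.tsv")
    tio.write_cells(cells, out / "cells.tsv")
    tio.write_trials(trials, out / "trials.tsv")
    tio.write_truth(truth, out / "truth.json")

    return dataclasses.replace(
        config,
        annotation=str(out / "annotation.tsv"),
        depth=str(out / "depth.bedgraph"),
        counts_eu=str(out / "counts_eu.tsv"),
        counts_tc=str(out / "counts_tc.tsv"),
        library_sizes=str(out / "library_sizes.tsv"),
        cells=str(out / "cells.tsv"),
        trials=str(out / "trials.tsv"),
        truth=str(out / "truth.json"),
    )


def _stage_deletions(config: PipelineConfig, out: Path) -> dict:
    annotation = tio.read_annotation(_require(config.annotation, "annotation", "deletions"))
    profile = tio.read_bedgraph(_require(config.depth, "depth", "deletions"))
    normalized = gen.normalize_depth(profile)
    calls = gen.call_deletions(
        normalized,
        threshold=config.deletion_threshold,
        min_bins=config.deletion_min_bins,
        merge_gap_bins=config.deletion_merge_gap_bins,
    )
    span = int(annotation["end"].max() - annotation["start"].min() + 1)
    summary = gen.annotate_deletions(calls, annotation, span_bp=span)
    tio.write_bed(calls, out / "deletions.bed")
    return {
        "n_calls": len(calls),
        "calls": [
            {"start": c.start, "end": c.end, "length": c.length, "n_bins": c.n_bins}
            for c in calls
        ],
        "n_deleted_pcg": summary["n_deleted_pcg"],
        "n_deleted_npcg": summary["n_deleted_npcg"],
        "fraction_span_deleted": round(summary["fraction_span_deleted"], 6),
        "deleted_genes": summary["deleted_genes"],
    }


def _stage_dosage(config: PipelineConfig, out: Path, deleted_genes: list[str]) -> dict:
    annotation = tio.read_annotation(_require(config.annotation, "annotation", "dosage"))
    eu = tio.read_counts(_require(config.counts_eu, "euploid counts", "dosage"))
    tc = tio.read_counts(_require(config.counts_tc, "trisomic counts", "dosage"))
    libs = tio.read_library_sizes(
        _require(config.library_sizes, "library sizes", "dosage")
    )
    eu_libs = {k: v for k, v in libs.items() if k.startswith("Eu")}
    tc_libs = {k: v for k, v in libs.items() if k.startswith("Tc")}
    eu_fpkm = dos.fpkm_table(eu, eu_libs)
    tc_fpkm = dos.fpkm_table(tc, tc_libs)

    pairs = annotation[
        (annotation["biotype"] == "PCG")
        & (annotation["family"] == "other")
        & (annotation["ortholog_id"] != "")
    ]
    records = dos.dosage_records(
        pairs, tc_fpkm, tc_fpkm, eu_fpkm, min_fpkm=config.min_fpkm,
        exclude=set(deleted_genes),
    )
    summary = dos.summarize_dosage(records)

    host_mask_eu = eu["compartment"] == "host" if "compartment" in eu else ~eu[
        "gene_id"
    ].isin(set(annotation["gene_id"]) | set(annotation["ortholog_id"]))
    host_mask_tc = tc["compartment"] == "host" if "compartment" in tc else ~tc[
        "gene_id"
    ].isin(set(annotation["gene_id"]) | set(annotation["ortholog_id"]))
    dys = dos.count_dysregulated(
        eu_fpkm[eu.loc[host_mask_eu, "gene_id"]],
        tc_fpkm[tc.loc[host_mask_tc, "gene_id"]],
        min_fpkm=config.min_fpkm,
        low=config.dysregulation_low,
        high=config.dysregulation_high,
    )
    silence = dos.validate_deleted_silence(tc_fpkm, set(deleted_genes))

    rec_table = [dataclasses.asdict(r) for r in records]
    with open(out / "dosage_records.tsv", "w") as fh:
        if rec_table:
            cols = list(rec_table[0])
            fh.write("\t".join(cols) + "\n")
            for r in rec_table:
                fh.write("\t".join(f"{r[c]:.6g}" if isinstance(r[c], float) else str(r[c]) for c in cols) + "\n")
    summary["dysregulation"] = {
        k: dys[k] for k in ("n_tested", "n_down", "n_up")
    }
    summary["deleted_silence"] = {
        "passed": silence["passed"],
        "violations": silence["violations"],
    }
    summary["dosage_class_proportions"] = {
        k: round(v, 6) for k, v in summary["dosage_class_proportions"].items()
    }
    return summary


def _stage_retention(config: PipelineConfig, out: Path) -> dict:
    cells = tio.read_cells(_require(config.cells, "cells", "retention"))
    obs = [
        ret.TissueRetention(
            tissue=tissue,
            n_cells=int(len(grp)),
            n_positive=int(grp["detected"].sum()),
        )
        for tissue, grp in cells.groupby("tissue", sort=True)
    ]
    pooled, per_tissue = ret.pool_retention(obs, conf=config.retention_conf)
    mosaic = [ret.test_mosaicism(o, threshold=config.mosaic_threshold) for o in obs]
    rows = []
    for o in obs:
        est = per_tissue[o.tissue]
        rows.append(
            f"{o.tissue}\t{o.n_cells}\t{o.n_positive}\t{est.p_hat:.6g}"
            f"\t{est.ci_low:.6g}\t{est.ci_high:.6g}"
        )
    (out / "retention.tsv").write_text(
        "tissue\tn_cells\tn_positive\tp_hat\tci_low\tci_high\n"
        + "\n".join(rows)
        + "\n"
    )
    return {
        "pooled": {
            "p_hat": round(pooled.p_hat, 6),
            "ci_low": round(pooled.ci_low, 6),
            "ci_high": round(pooled.ci_high, 6),
            "n_cells": pooled.n_cells,
        },
        "min_tissue_p_hat": round(min(e.p_hat for e in per_tissue.values()), 6),
        "per_tissue": {
            t: {
                "p_hat": round(e.p_hat, 6),
                "ci_low": round(e.ci_low, 6),
                "ci_high": round(e.ci_high, 6),
            }
            for t, e in sorted(per_tissue.items())
        },
        "mosaic_suspect_tissues": sorted(
            m["tissue"] for m in mosaic if m["mosaic_suspect"]
        ),
    }


def _stage_behavior(config: PipelineConfig, out: Path) -> dict:
    trials = tio.read_trials(_require(config.trials, "trials", "behavior"))
    summary = beh.retained_memory_summary(trials)
    summary.to_csv(out / "retained_memory.tsv", sep="\t", index=False)
    return {
        "chance_level_circular_pct": round(100 * beh.chance_level_circular(), 4),
        "chance_level_open_field_pct": round(
            100 * beh.chance_level_square(37.0, 21.6), 4
        ),
        "retained_memory_mean_pct": {
            int(day): round(val, 4)
            for day, val in zip(summary["day"], summary["mean_retained_pct"])
        },
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; write per-stage outputs and one report.json."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    if config.simulate:
        try:
            config = simulate_inputs(config)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage tagging
            raise PipelineError("simulate", str(exc)) from exc

    for stage, fn in [
        ("deletions", lambda: _stage_deletions(config, out)),
        (
            "dosage",
            lambda: _stage_dosage(
                config, out, report.get("deletions", {}).get("deleted_genes", [])
            ),
        ),
        ("retention", lambda: _stage_retention(config, out)),
        ("behavior", lambda: _stage_behavior(config, out)),
    ]:
        log.info("stage %s", stage)
        try:
            report[stage] = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage tagging
            raise PipelineError(stage, str(exc)) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
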