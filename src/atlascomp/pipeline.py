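"""Config-driven end-to-end orchestration with provenance.

Stages run in a fixed order — simulate, harmonise, fit, test, adjust,
trajectories, communication — each persisting its artifacts under the run
directory. The manifest records the seed, a config hash, per-stage row
counts and a content hash for every output file, so a re-run with the same
config and seed reproduces deterministic artifacts byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adjusted_views, communication, harmonise, multilevel, synthetic_atlas
from .containers import CompositionMatrix
from .design import DesignSpec, build_design


@dataclass
class RunConfig:
    output_dir: str = "results/run"
    seed: int = 0
    analysis: str = "age"
    mode: str = "composition"
    # exactly one of synthetic / input_paths drives the run
    synthetic: dict | None = field(default_factory=dict)
    input_paths: dict | None = None
    truth: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    null_halfwidth: float = 0.2
    fdr_threshold: float = 0.05
    communication: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_paths is None):
            raise ValueError("exactly one of synthetic / input_paths must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        payload = json.dumps(asdict(config), sort_keys=True, default=str)
        self.data = {
            "seed": config.seed,
            "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
            "stages": {},
            "files": {},
        }

    def record(self, stage: str, rows: dict, files: list[Path]) -> None:
        self.data["stages"][stage] = {"row_counts": rows, "status": "ok"}
        for f in files:
            self.data["files"][str(f.relative_to(self.outdir))] = _sha256(f)

    def fail(self, stage: str, error: Exception) -> None:
        self.data["stages"][stage] = {"status": "failed", "error": str(error)}

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    A stage failure is recorded in the manifest and re-raised, halting the
    run with the failing stage named.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("harmonise", _stage_harmonise),
        ("fit", _stage_fit),
        ("test", _stage_test),
        ("adjust", _stage_adjust),
        ("trajectories", _stage_trajectories),
        ("communication", _stage_communication),
    ]
    try:
        for name, stage_fn in stages:
            rows, files = stage_fn(config, state, outdir)
            manifest.record(name, rows, files)
    except Exception as err:
        manifest.fail(name, err)
        manifest.write()
        raise
    manifest.write()
    return manifest.data


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, outdir: Path):
    if config.input_paths is not None:
        samples = pd.read_csv(config.input_paths["samples"])
        cells = pd.read_csv(config.input_paths["cells"])
        state.update(samples=samples, cells=cells, truth=None)
        return ({"samples": len(samples), "cells": len(cells)}, [])
    cfg = synthetic_atlas.AtlasConfig(**(config.synthetic or {}))
    samples = synthetic_atlas.generate_sample_frame(cfg, config.seed)
    n_datasets = samples["dataset_id"].nunique()
    truth = synthetic_atlas.GroundTruth.random(
        n_categories=cfg.n_categories, n_tissues=cfg.n_tissues,
        n_datasets=n_datasets, seed=config.seed, **config.truth)
    spec = _design_spec(config)
    counts = synthetic_atlas.generate_counts(samples, truth, spec, config.seed,
                                             categories=cfg.categories())
    cells = synthetic_atlas.generate_cell_table(
        samples, counts, cfg.annotation_agreement, seed=config.seed)
    state.update(samples=samples, cells=cells, truth=truth, counts=counts,
                 atlas_config=cfg)
    samples.to_csv(outdir / "samples.csv", index=False)
    cells.to_csv(outdir / "cells.csv", index=False)
    counts.to_tsv(outdir / "counts_true.tsv")
    (outdir / "ground_truth.json").write_text(json.dumps({
        "beta": truth.beta.tolist(), "u_tissue": truth.u_tissue.tolist(),
        "v_dataset": truth.v_dataset.tolist(), "gamma": truth.gamma.tolist(),
        "gamma_base": truth.gamma_base.tolist(), "seed": truth.seed,
    }, indent=1))
    return ({"samples": len(samples), "cells": len(cells)},
            [outdir / "samples.csv", outdir / "cells.csv",
             outdir / "counts_true.tsv", outdir / "ground_truth.json"])


def _design_spec(config: RunConfig) -> DesignSpec:
    return DesignSpec(**config.design) if config.design else DesignSpec()


def _stage_harmonise(config: RunConfig, state: dict, outdir: Path):
    cells = harmonise.annotate_cells(state["cells"])
    th = harmonise.CohortThresholds(**config.thresholds)
    counts, design_table, attrition = harmonise.build_cohort(
        cells, state["samples"], analysis=config.analysis, mode=config.mode,
        thresholds=th)
    state.update(cohort_counts=counts, design_table=design_table,
                 attrition=attrition)
    counts.to_tsv(outdir / "counts_cohort.tsv")
    design_table.to_csv(outdir / "design_table.csv", index=False)
    attrition.to_csv(outdir / "attrition.tsv", sep="\t", index=False)
    return ({"samples": len(design_table),
             "attrition_total_excluded":
                 int(attrition["samples_excluded"].sum())},
            [outdir / "counts_cohort.tsv", outdir / "design_table.csv",
             outdir / "attrition.tsv"])


def _stage_fit(config: RunConfig, state: dict, outdir: Path):
    spec = _design_spec(config)
    design = build_design(state["design_table"], spec)
    options = multilevel.FitOptions(seed=config.seed, **config.fit)
    fit_ = multilevel.fit(state["cohort_counts"], design, options=options)
    state["fit"] = fit_
    diag = {"max_rhat": fit_.diagnostics["max_rhat"],
            "divergences": fit_.diagnostics["divergences"],
            "warnings": fit_.diagnostics["warnings"]}
    (outdir / "fit_diagnostics.json").write_text(json.dumps(diag, indent=1))
    return ({"draws": fit_.n_draws}, [outdir / "fit_diagnostics.json"])


def _stage_test(config: RunConfig, state: dict, outdir: Path):
    fit_ = state["fit"]
    frames = [multilevel.test_effects(fit_, "age_scaled", "body",
                                      config.null_halfwidth,
                                      config.fdr_threshold)]
    if fit_.design.groups:
        frames.append(multilevel.test_effects(fit_, "age_scaled", "tissue",
                                              config.null_halfwidth,
                                              config.fdr_threshold))
    effects = pd.concat(frames, ignore_index=True)
    state["effects"] = effects
    effects.to_csv(outdir / "effects.tsv", sep="\t", index=False)
    return ({"effects": len(effects)}, [outdir / "effects.tsv"])


def _stage_adjust(config: RunConfig, state: dict, outdir: Path):
    adjusted = adjusted_views.remove_unwanted_variation(
        state["fit"], state["cohort_counts"],
        target_fixed=["intercept", "age_scaled"]
        if "intercept" in state["fit"].design.term_columns else ["age_scaled"],
        target_groups=())
    state["adjusted"] = adjusted
    adjusted.to_csv(outdir / "adjusted_proportions.tsv", sep="\t",
                    index_label="sample_id")
    return ({"samples": len(adjusted)}, [outdir / "adjusted_proportions.tsv"])


def _stage_trajectories(config: RunConfig, state: dict, outdir: Path):
    traj = adjusted_views.ageing_trajectories(state["fit"])
    state["trajectories"] = traj
    traj.grid.to_csv(outdir / "trajectory_grid.tsv", sep="\t", index=False)
    traj.coordinates.to_csv(outdir / "trajectory_coordinates.tsv", sep="\t",
                            index=False)
    traj.loadings.to_csv(outdir / "trajectory_loadings.tsv", sep="\t",
                         index_label="category")
    return ({"grid_rows": len(traj.grid)},
            [outdir / "trajectory_grid.tsv",
             outdir / "trajectory_coordinates.tsv",
             outdir / "trajectory_loadings.tsv"])


def _stage_communication(config: RunConfig, state: dict, outdir: Path):
    samples = state["design_table"]
    cfg = config.communication or {}
    categories = state["cohort_counts"].categories
    slopes = cfg.get("truth_slopes",
                     {c: 0.0 for c in categories})
    records = synthetic_atlas.generate_communication_weights(
        samples, slopes, config.seed,
        cell_types=list(categories)[: cfg.get("n_cell_types", 3)])
    counts_long = state["cohort_counts"].counts.reset_index(names="sample_id") \
        .melt(id_vars="sample_id", var_name="cell_type", value_name="n_cells")
    eligible, attrition = communication.filter_communication(counts_long)
    keep = set(map(tuple, eligible[["sample_id", "cell_type"]].to_numpy()))
    records = records[[(s, c) in keep for s, c in
                       zip(records["sample_id"], records["sender"])]]
    strengths = communication.summarise_strength(records)
    opts = communication.WeightModelOptions(
        seed=config.seed, min_samples=cfg.get("min_samples", 5),
        draws=cfg.get("draws", 500))
    strengths = strengths.groupby(["tissue", "sender", "axis"]) \
        .filter(lambda g: g["sample_id"].nunique() >= opts.min_samples)
    results = communication.fit_weight_model(strengths, opts) \
        if not strengths.empty else pd.DataFrame()
    state["communication"] = results
    results.to_csv(outdir / "communication_effects.tsv", sep="\t", index=False)
    attrition.to_csv(outdir / "communication_attrition.tsv", sep="\t",
                     index=False)
    return ({"tested": len(results)},
            [outdir / "communication_effects.tsv",
             outdir / "communication_attrition.tsv"])
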