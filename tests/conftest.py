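"""Shared fixtures and simulation harnesses for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from atlascomp import multilevel as ml
from atlascomp import synthetic_atlas as sa
from atlascomp.design import DesignSpec, build_design


def make_recovery_setup(seed: int, *, n_categories: int = 4, n_tissues: int = 10,
                        datasets_per_tissue: int = 2, samples_per_dataset: int = 10,
                        slope: float = 1.0, cells=(200, 1000), **truth_kw):
    """Synthetic atlas with a known body-level age slope on category 0.

    Returns (samples, truth, counts, design); the generating age coefficient
    row is ``slope`` on category 0 and balanced on the rest (centred).
    """
    cfg = sa.AtlasConfig(
        n_tissues=n_tissues, datasets_per_tissue=datasets_per_tissue,
        samples_per_dataset=samples_per_dataset, n_categories=n_categories,
        cells_per_sample_range=cells)
    samples = sa.generate_sample_frame(cfg, seed)
    truth = sa.GroundTruth.random(
        n_categories, n_tissues, samples["dataset_id"].nunique(), seed=seed,
        **truth_kw)
    row = np.full(n_categories, -slope / (n_categories - 1))
    row[0] = slope
    truth.beta[1] = row
    truth.beta = truth.beta - truth.beta.mean(axis=1, keepdims=True)
    counts = sa.generate_counts(samples, truth, DesignSpec(), seed,
                                categories=cfg.categories())
    design = build_design(samples, DesignSpec())
    return samples, truth, counts, design


def quick_fit(counts, design, seed: int, **kw) -> ml.ModelFit:
    opts = ml.FitOptions(seed=seed, draws=kw.pop("draws", 250), **kw)
    return ml.fit(counts, design, options=opts)


@pytest.fixture(scope="session")
def small_atlas():
    """A small but non-trivial synthetic atlas shared across fast tests."""
    seed = 42
    cfg = sa.AtlasConfig(n_tissues=3, datasets_per_tissue=2,
                         samples_per_dataset=8, n_categories=4,
                         cells_per_sample_range=(100, 300))
    samples = sa.generate_sample_frame(cfg, seed)
    truth = sa.GroundTruth.random(4, 3, samples["dataset_id"].nunique(),
                                  seed=seed)
    counts = sa.generate_counts(samples, truth, DesignSpec(), seed,
                                categories=cfg.categories())
    return {"config": cfg, "samples": samples, "truth": truth,
            "counts": counts, "seed": seed}


@pytest.fixture(scope="session")
def small_fit(small_atlas):
    design = build_design(small_atlas["samples"], DesignSpec())
    return quick_fit(small_atlas["counts"], design, small_atlas["seed"])


@pytest.fixture()
def toy_cells_and_samples():
    """Hand-built toy cohort exercising the filtering rules."""
    def sample_row(sid, dataset="d1", tissue="lung", age=40 * 365.0,
                   sex="female", eth="European", assay="10x 3' v2",
                   primary=True, healthy=True):
        return dict(sample_id=sid, dataset_id=dataset, tissue_harmonised=tissue,
                    age_days=age, sex=sex, ethnicity=eth, assay=assay,
                    is_primary=primary, is_healthy=healthy)

    samples = pd.DataFrame([
        sample_row("s_ok1"), sample_row("s_ok2"), sample_row("s_ok3"),
        sample_row("s_small"),                       # 25 cells -> rule 2
        sample_row("s_sick", healthy=False),         # rule 1
        sample_row("s_dense"),                       # cellularity 0.8 -> rule 8
    ])

    def cells_for(sid, n_immune, n_other, label="T cell"):
        rows = []
        for i in range(n_immune):
            rows.append(dict(cell_id=f"{sid}_i{i}", sample_id=sid,
                             label_source_1=label, label_source_2=label,
                             label_source_3=label, label_source_4=label,
                             is_immune=True))
        for i in range(n_other):
            rows.append(dict(cell_id=f"{sid}_n{i}", sample_id=sid,
                             label_source_1="non_immune",
                             label_source_2="non_immune",
                             label_source_3="non_immune",
                             label_source_4="non_immune", is_immune=False))
        return rows

    cells = pd.DataFrame(
        cells_for("s_ok1", 20, 20) + cells_for("s_ok2", 15, 25, "B cell")
        + cells_for("s_ok3", 10, 30) + cells_for("s_small", 10, 15)
        + cells_for("s_sick", 20, 20) + cells_for("s_dense", 32, 8))
    return cells, samples
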