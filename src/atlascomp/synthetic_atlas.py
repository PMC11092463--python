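"""Synthetic immune-atlas generator with recorded ground truth.

Emulates the hierarchical structure of a multi-study cell atlas — tissues
containing datasets containing samples containing cells — together with the
distributional features the compositional model assumes: sum-constrained
overdispersed counts whose means follow a softmax-linear model, precision
following a log-linear model, outlier contamination, and noisy multi-source
cell annotations with a controlled consensus-tier distribution.

Every generator is deterministic given its seed; one global seed fans out to
per-operation substreams via :func:`numpy.random.SeedSequence.spawn`-style
keyed seeding so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import expit, softmax
from .containers import CompositionMatrix
from .design import Design, DesignSpec, build_design


class ConfigError(ValueError):
    """Invalid generator configuration; names the offending field."""


class GenerationError(RuntimeError):
    """Non-finite linear predictor or non-positive precision."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Substream RNG keyed by (seed, stream name)."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stream.encode(), "little") % (2**63)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class AtlasConfig:
    n_tissues: int = 10
    datasets_per_tissue: int = 2
    samples_per_dataset: int = 10
    cells_per_sample_range: tuple[int, int] = (200, 2000)
    n_categories: int = 4
    multi_tissue_fraction: float = 0.262
    age_range_by_tissue: dict[str, tuple[float, float]] | None = None
    default_age_range_days: tuple[float, float] = (8 * 365.0, 84 * 365.0)
    sex_frequencies: dict[str, float] = field(
        default_factory=lambda: {"female": 0.5, "male": 0.5})
    ethnicity_frequencies: dict[str, float] = field(
        default_factory=lambda: {"European": 0.6, "Asian": 0.2,
                                 "African": 0.1, "Hispanic": 0.1})
    technology_frequencies: dict[str, float] = field(
        default_factory=lambda: {"10x": 0.8, "smart-seq2": 0.2})
    annotation_agreement: tuple[float, float, float, float] = (0.87, 0.05, 0.05, 0.03)

    def validate(self) -> None:
        for name in ("n_tissues", "datasets_per_tissue", "samples_per_dataset",
                     "n_categories"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        lo, hi = self.cells_per_sample_range
        if not (0 < lo <= hi):
            raise ConfigError("cells_per_sample_range must be a non-empty "
                              "positive interval")
        if not (0.0 <= self.multi_tissue_fraction <= 1.0):
            raise ConfigError("multi_tissue_fraction must lie in [0, 1]")
        for name in ("sex_frequencies", "ethnicity_frequencies",
                     "technology_frequencies"):
            freqs = getattr(self, name)
            p = np.array(list(freqs.values()), dtype=float)
            if np.any(p < 0) or np.any(p > 1) or not np.isclose(p.sum(), 1.0):
                raise ConfigError(f"{name} must be probabilities summing to 1")
        agree = np.asarray(self.annotation_agreement, dtype=float)
        if agree.shape != (4,) or np.any(agree < 0) or not np.isclose(agree.sum(), 1.0):
            raise ConfigError("annotation_agreement must be 4 probabilities "
                              "summing to 1")

    def categories(self) -> list[str]:
        return [f"type_{i}" for i in range(self.n_categories)]

    def tissues(self) -> list[str]:
        return [f"tissue_{i:02d}" for i in range(self.n_tissues)]


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=-1, keepdims=True)


@dataclass
class GroundTruth:
    """True coefficients behind a synthetic atlas.

    ``beta`` rows (one per fixed covariate) and all group-level coefficient
    rows sum to zero across categories — the softmax identifiability
    convention shared with the fitted model. ``gamma`` holds the
    category-specific (centred) log-precision coefficients; the category-wide
    baseline log precision lives in ``gamma_base``, since a fully centred
    precision row would pin the geometric-mean precision to one.
    """

    beta: np.ndarray                 # (n_fixed_cov, K) sum-to-zero rows
    u_tissue: np.ndarray             # (n_tissues, n_rand_cov, K) sum-to-zero
    v_dataset: np.ndarray            # (n_datasets, K) sum-to-zero rows
    gamma: np.ndarray                # (n_var_cov, K) centred rows
    gamma_base: np.ndarray           # (n_var_cov,) baseline log precision
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = _center(np.atleast_2d(np.asarray(self.beta, dtype=float)))
        self.u_tissue = _center(np.asarray(self.u_tissue, dtype=float))
        self.v_dataset = _center(np.atleast_2d(np.asarray(self.v_dataset, dtype=float)))
        self.gamma = _center(np.atleast_2d(np.asarray(self.gamma, dtype=float)))
        self.gamma_base = np.asarray(self.gamma_base, dtype=float)
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigError("outlier_rate must lie in [0, 1]")

    @property
    def n_categories(self) -> int:
        return self.beta.shape[1]

    @classmethod
    def null(cls, n_categories: int, n_fixed: int = 2, n_tissues: int = 10,
             n_rand: int = 2, n_datasets: int = 20,
             log_precision: float = 4.0, seed: int = 0) -> "GroundTruth":
        """All effects zero; constant precision exp(log_precision)."""
        return cls(
            beta=np.zeros((n_fixed, n_categories)),
            u_tissue=np.zeros((n_tissues, n_rand, n_categories)),
            v_dataset=np.zeros((n_datasets, n_categories)),
            gamma=np.zeros((1, n_categories)),
            gamma_base=np.array([log_precision]),
            seed=seed,
        )

    @classmethod
    def random(cls, n_categories: int, n_tissues: int, n_datasets: int,
               seed: int, *, n_fixed: int = 2, n_rand: int = 2,
               intercept_scale: float = 1.0, slope_scale: float = 0.75,
               tissue_intercept_sd: float = 0.5, tissue_slope_sd: float = 0.25,
               dataset_sd: float = 0.3, log_precision: float = 4.0,
               outlier_rate: float = 0.0) -> "GroundTruth":
        """Draw a realistic random truth with the stated variance components."""
        rng = _rng(seed, "truth")
        beta = np.zeros((n_fixed, n_categories))
        beta[0] = rng.normal(0.0, intercept_scale, n_categories)
        for j in range(1, n_fixed):
            beta[j] = rng.normal(0.0, slope_scale, n_categories)
        u = np.zeros((n_tissues, n_rand, n_categories))
        u[:, 0, :] = rng.normal(0.0, tissue_intercept_sd, (n_tissues, n_categories))
        for j in range(1, n_rand):
            u[:, j, :] = rng.normal(0.0, tissue_slope_sd, (n_tissues, n_categories))
        v = rng.normal(0.0, dataset_sd, (n_datasets, n_categories))
        return cls(
            beta=beta, u_tissue=u, v_dataset=v,
            gamma=np.zeros((1, n_categories)),
            gamma_base=np.array([log_precision]),
            outlier_rate=outlier_rate, seed=seed,
        )


# ---------------------------------------------------------------------------
# sample frame
# ---------------------------------------------------------------------------

def generate_sample_frame(config: AtlasConfig, seed: int) -> pd.DataFrame:
    """Draw the sample table of a synthetic atlas.

    Samples nest in datasets nest in tissues; a configurable fraction of
    datasets spans two tissues (mirroring multi-tissue studies in real
    atlases). Age is drawn uniformly in days within the tissue's range; sex,
    ethnicity and technology from the configured frequencies.
    """
    config.validate()
    rng = _rng(seed, "samples")
    tissues = config.tissues()
    age_ranges = dict(config.age_range_by_tissue or {})
    rows = []
    n_datasets = config.n_tissues * config.datasets_per_tissue
    multi = rng.random(n_datasets) < config.multi_tissue_fraction
    d = 0
    for t_i, tissue in enumerate(tissues):
        for _ in range(config.datasets_per_tissue):
            dataset_id = f"dataset_{d:03d}"
            span = [tissue]
            if multi[d] and config.n_tissues > 1:
                other = tissues[(t_i + 1 + rng.integers(config.n_tissues - 1))
                                % config.n_tissues]
                span.append(other)
            for s in range(config.samples_per_dataset):
                s_tissue = span[s % len(span)]
                lo, hi = age_ranges.get(s_tissue, config.default_age_range_days)
                if not hi >= lo:
                    raise ConfigError(
                        f"age_range_by_tissue[{s_tissue!r}] is empty")
                rows.append({
                    "sample_id": f"{dataset_id}_s{s:03d}",
                    "dataset_id": dataset_id,
                    "tissue_harmonised": s_tissue,
                    "age_days": float(rng.uniform(lo, hi)),
                    "sex": _draw_level(rng, config.sex_frequencies),
                    "ethnicity": _draw_level(rng, config.ethnicity_frequencies),
                    "assay": _draw_level(rng, config.technology_frequencies),
                    "is_primary": True,
                    "is_healthy": True,
                    "n_cells": int(rng.integers(config.cells_per_sample_range[0],
                                                config.cells_per_sample_range[1] + 1)),
                    "spans_multiple_tissues": len(span) > 1,
                })
            d += 1
    frame = pd.DataFrame(rows)
    age = frame["age_days"]
    sd = age.std(ddof=0)
    frame["age_scaled"] = 0.0 if sd == 0 else (age - age.mean()) / sd
    return frame


def _draw_level(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    names = list(freqs)
    return names[rng.choice(len(names), p=np.array(list(freqs.values())))]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(
    samples: pd.DataFrame,
    truth: GroundTruth,
    design: DesignSpec | Design,
    seed: int,
    *,
    family: str = "renorm_beta",
    categories: list[str] | None = None,
) -> CompositionMatrix:
    """Draw per-sample category counts from the generative model.

    For each sample the linear predictor combines the fixed covariates with
    the tissue-level and dataset-level coefficients of ``truth``; the mean is
    its softmax, the precision is log-linear in the variability covariates.
    ``family="renorm_beta"`` draws independent Beta proportions and
    renormalises before the multinomial draw (the generative counterpart of
    the fitted beta-binomial likelihood); ``family="dirichlet_multinomial"``
    is provided as a robustness switch.
    """
    if isinstance(design, DesignSpec):
        design = build_design(samples, design)
    K = truth.n_categories
    categories = categories or [f"type_{i}" for i in range(K)]
    if len(categories) != K:
        raise ConfigError("categories must match truth.n_categories")

    eta = design.X @ truth.beta
    for gname, g in design.groups.items():
        if gname.startswith("tissue"):
            coef = truth.u_tissue  # (L, T, K)
            if coef.shape[0] < g.n_levels or coef.shape[1] < g.n_terms:
                raise ConfigError("truth.u_tissue too small for the design")
            eta += np.einsum("nt,ntk->nk", g.slopes,
                             coef[g.index][:, :g.n_terms, :])
        elif gname.startswith("dataset"):
            if truth.v_dataset.shape[0] < g.n_levels:
                raise ConfigError("truth.v_dataset too small for the design")
            eta += truth.v_dataset[g.index] * g.slopes[:, :1]
    n_var = design.Xv.shape[1]
    if truth.gamma.shape[0] < n_var or truth.gamma_base.shape[0] < n_var:
        raise ConfigError("truth.gamma/gamma_base too small for the "
                          "variability design")
    log_phi = design.Xv @ (truth.gamma_base[:n_var, None] + truth.gamma[:n_var])
    if not np.all(np.isfinite(eta)) or not np.all(np.isfinite(log_phi)):
        raise GenerationError("non-finite linear predictor")
    phi = np.exp(log_phi)
    if np.any(phi <= 0):
        raise GenerationError("non-positive precision")

    mu = softmax(eta, axis=1)
    rng = _rng(seed, "counts")
    totals = samples["n_cells"].to_numpy(dtype=int)
    if family == "renorm_beta":
        p = rng.beta(mu * phi, (1.0 - mu) * phi)
        p = np.clip(p, 1e-12, None)
        p /= p.sum(axis=1, keepdims=True)
    elif family == "dirichlet_multinomial":
        p = np.vstack([rng.dirichlet(c) for c in mu * phi])
    else:
        raise ConfigError(f"unknown family {family!r}")
    counts = np.vstack([rng.multinomial(n, pi) for n, pi in zip(totals, p)])
    return CompositionMatrix(pd.DataFrame(
        counts, index=samples["sample_id"].astype(str).tolist(),
        columns=categories))


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------

def inject_outliers(
    counts: CompositionMatrix,
    rate: float,
    magnitude: float,
    seed: int,
) -> tuple[CompositionMatrix, pd.DataFrame]:
    """Multiply or divide a random ``rate`` fraction of (sample, category)
    counts by ``magnitude``; totals are re-adjusted to the contaminated sums.

    Returns the contaminated matrix and a boolean flag frame of true
    outliers.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("rate must lie in [0, 1]")
    if magnitude <= 0:
        raise ConfigError("magnitude must be positive")
    y = counts.counts.to_numpy().copy().astype(int)
    rng = _rng(seed, "outliers")
    flags = rng.random(y.shape) < rate
    up = rng.random(y.shape) < 0.5
    new = np.where(up, np.ceil(y * magnitude), np.floor(y / magnitude)).astype(int)
    # guarantee every flagged entry visibly differs from the original
    new = np.where(new == y, np.where(up, y + int(np.ceil(magnitude)),
                                      np.maximum(y - int(np.ceil(magnitude)), 0)), new)
    new = np.where((new == y), y + int(np.ceil(magnitude)), new)
    new = np.where(flags, new, y)
    out = CompositionMatrix(pd.DataFrame(
        new.astype(int), index=counts.counts.index, columns=counts.counts.columns))
    flag_df = pd.DataFrame(flags, index=counts.counts.index,
                           columns=counts.counts.columns)
    return out, flag_df


# ---------------------------------------------------------------------------
# cell table
# ---------------------------------------------------------------------------

def generate_cell_table(
    samples: pd.DataFrame,
    counts: CompositionMatrix,
    annotation_agreement: tuple[float, float, float, float],
    label_ontology: list[str] | None = None,
    seed: int = 0,
    *,
    non_immune_labels: frozenset[str] = frozenset({"non_immune"}),
) -> pd.DataFrame:
    """Expand counts into one row per cell with four noisy source labels.

    Each cell draws a consensus tier from ``annotation_agreement``:
    tier 1 — all four sources carry the true label; tier 2 — one source
    disagrees; tier 3 — two sources disagree (with two distinct wrong
    labels, so the true label stays modal); tier 4 — all four sources
    mutually disagree (no consensus).
    """
    agree = np.asarray(annotation_agreement, dtype=float)
    if agree.shape != (4,) or np.any(agree < 0) or not np.isclose(agree.sum(), 1.0):
        raise ConfigError("annotation_agreement must be 4 probabilities summing to 1")
    categories = counts.categories
    ontology = list(label_ontology) if label_ontology else list(categories)
    extra = [f"distractor_{i}" for i in range(max(0, 4 - len(ontology)))]
    ontology = ontology + extra
    rng = _rng(seed, "cells")

    y = counts.counts.to_numpy().astype(int)
    sample_ids = counts.sample_ids
    rows_sample, rows_true = [], []
    for s, sid in enumerate(sample_ids):
        for k, cat in enumerate(categories):
            rows_sample.extend([sid] * y[s, k])
            rows_true.extend([cat] * y[s, k])
    n = len(rows_true)
    tiers = rng.choice(4, size=n, p=agree) + 1
    labels = np.empty((n, 4), dtype=object)
    for i in range(n):
        true = rows_true[i]
        wrong_pool = [l for l in ontology if l != true]
        t = tiers[i]
        lab = [true] * 4
        if t == 2:
            pos = rng.integers(1, 4)  # keep the original (priority) source true
            lab[pos] = wrong_pool[rng.integers(len(wrong_pool))]
        elif t == 3:
            w = rng.choice(len(wrong_pool), size=2, replace=False)
            pos = rng.choice([1, 2, 3], size=2, replace=False)
            lab[pos[0]] = wrong_pool[w[0]]
            lab[pos[1]] = wrong_pool[w[1]]
        elif t == 4:
            w = rng.choice(len(wrong_pool), size=3, replace=False)
            lab = [true] + [wrong_pool[j] for j in w]
        labels[i] = lab
    frame = pd.DataFrame({
        "cell_id": [f"cell_{i:07d}" for i in range(n)],
        "sample_id": rows_sample,
        "true_label": rows_true,
        "label_source_1": labels[:, 0],
        "label_source_2": labels[:, 1],
        "label_source_3": labels[:, 2],
        "label_source_4": labels[:, 3],
    })
    frame["is_immune"] = ~frame["true_label"].isin(non_immune_labels)
    return frame


# ---------------------------------------------------------------------------
# communication weights
# ---------------------------------------------------------------------------

def generate_communication_weights(
    samples: pd.DataFrame,
    truth_slope: dict[str, float],
    seed: int,
    *,
    axes: list[str] | None = None,
    cell_types: list[str] | None = None,
    intercept: float = -1.0,
    dataset_sd: float = 0.3,
    kappa: float = 40.0,
) -> pd.DataFrame:
    """Draw pairwise cell-communication weights with a Beta noise model.

    logit of the mean weight is linear in scaled age (slope per sender cell
    type) plus a dataset-level intercept; weights are strictly inside (0, 1).
    """
    cell_types = cell_types or sorted(truth_slope)
    axes = axes or ["axis_1"]
    rng = _rng(seed, "communication")
    datasets = sorted(samples["dataset_id"].astype(str).unique())
    b_dataset = dict(zip(datasets, rng.normal(0.0, dataset_sd, len(datasets))))
    rows = []
    eps = 1e-6
    for _, s in samples.iterrows():
        for axis in axes:
            for sender in cell_types:
                for receiver in cell_types:
                    if receiver == sender:
                        continue
                    mu = expit(intercept
                               + truth_slope.get(sender, 0.0) * s["age_scaled"]
                               + b_dataset[str(s["dataset_id"])])
                    w = float(np.clip(rng.beta(mu * kappa, (1 - mu) * kappa),
                                      eps, 1 - eps))
                    rows.append({
                        "sample_id": s["sample_id"],
                        "tissue": s["tissue_harmonised"],
                        "dataset_id": s["dataset_id"],
                        "sender": sender,
                        "receiver": receiver,
                        "axis": axis,
                        "weight": w,
                        "age_days": s["age_days"],
                        "age_scaled": s["age_scaled"],
                    })
    return pd.DataFrame(rows)
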