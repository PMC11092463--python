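"""Design matrices for the multilevel compositional model.

A :class:`DesignSpec` names the population-level (fixed) covariates, the
variability covariates, and the group-level (random) terms as pairs of
(grouping column, slope covariates) — for example ``("tissue", ["intercept",
"age_scaled"])`` gives every tissue its own partially pooled intercept and
age slope, while ``("dataset", ["intercept"])`` gives every dataset a random
intercept.

Categorical covariates are dummy-coded against a declared baseline (females
are the conventional baseline for sex); a covariate may instead be declared
``intercept_free``, in which case it is cell-means coded with one indicator
per level and no global intercept, as used for ethnicity contrasts.
Interactions are written ``"a:b"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ConfoundingError(ValueError):
    """Raised when fixed-design columns are linearly aliased."""


@dataclass
class DesignSpec:
    fixed_terms: list[str] = field(default_factory=lambda: ["intercept", "age_scaled"])
    variability_terms: list[str] = field(default_factory=lambda: ["intercept"])
    random_terms: list[tuple[str, list[str]]] = field(
        default_factory=lambda: [("tissue_harmonised", ["intercept", "age_scaled"]),
                                 ("dataset_id", ["intercept"])]
    )
    baselines: dict[str, str] = field(default_factory=dict)
    intercept_free: str | None = None  # covariate coded with all levels, no intercept

    def __post_init__(self) -> None:
        if self.intercept_free is not None and "intercept" in self.fixed_terms:
            raise ValueError(
                "intercept_free designs must not also list an 'intercept' term"
            )


@dataclass
class GroupDesign:
    """Random-effect structure for one grouping factor."""

    name: str
    levels: list[str]
    term_names: list[str]          # encoded slope-column names
    index: np.ndarray              # (n,) integer level index per sample
    slopes: np.ndarray             # (n, T) encoded slope values per sample

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_terms(self) -> int:
        return len(self.term_names)


@dataclass
class Design:
    X: np.ndarray                  # (n, P) fixed design
    x_names: list[str]
    Xv: np.ndarray                 # (n, Pv) variability design
    xv_names: list[str]
    groups: dict[str, GroupDesign]
    term_columns: dict[str, list[int]]   # fixed term -> column indices in X
    sample_ids: list[str]
    levels: dict[str, list[str]]   # categorical covariate -> training levels
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def encode_rows(self, rows: pd.DataFrame) -> np.ndarray:
        """Encode new covariate rows into the fixed design's column space.

        Missing covariates default to the baseline level (categoricals) or
        zero (numerics). Unseen categorical levels are an error.
        """
        out = np.zeros((len(rows), len(self.x_names)))
        for term, cols in self.term_columns.items():
            block, _ = _encode_term(
                term, rows, self.metadata["baselines"], self.levels,
                self.metadata.get("intercept_free"), strict=True, defaults=True,
            )
            out[:, cols] = block
        return out


def _levels_of(values: pd.Series) -> list[str]:
    return sorted(map(str, pd.unique(values.dropna())))


def _encode_single(
    name: str,
    rows: pd.DataFrame,
    baselines: dict[str, str],
    levels: dict[str, list[str]],
    intercept_free: str | None,
    strict: bool,
    defaults: bool,
) -> tuple[np.ndarray, list[str]]:
    n = len(rows)
    if name == "intercept":
        return np.ones((n, 1)), ["intercept"]
    if name not in rows.columns:
        if defaults:
            if name in levels:  # categorical at baseline
                k = len(_dummy_levels(name, levels, baselines, intercept_free))
                return np.zeros((n, k)), _dummy_names(name, levels, baselines, intercept_free)
            return np.zeros((n, 1)), [name]
        raise KeyError(f"covariate {name!r} not found in sample table")
    col = rows[name]
    if pd.api.types.is_numeric_dtype(col) and name not in levels:
        return col.to_numpy(dtype=float)[:, None], [name]
    # categorical
    if name not in levels:
        levels[name] = _levels_of(col)
    lv = levels[name]
    vals = col.astype(str)
    unseen = set(vals) - set(lv)
    if unseen and strict:
        raise ValueError(f"unseen level(s) {sorted(unseen)} for covariate {name!r}")
    keep = _dummy_levels(name, levels, baselines, intercept_free)
    block = np.column_stack([(vals == l).to_numpy(dtype=float) for l in keep]) \
        if keep else np.zeros((n, 0))
    return block, _dummy_names(name, levels, baselines, intercept_free)


def _dummy_levels(name, levels, baselines, intercept_free) -> list[str]:
    lv = levels[name]
    if intercept_free == name:
        return list(lv)
    base = baselines.get(name, lv[0])
    return [l for l in lv if l != base]


def _dummy_names(name, levels, baselines, intercept_free) -> list[str]:
    return [f"{name}[{l}]" for l in _dummy_levels(name, levels, baselines, intercept_free)]


def _encode_term(
    term: str,
    rows: pd.DataFrame,
    baselines: dict[str, str],
    levels: dict[str, list[str]],
    intercept_free: str | None,
    strict: bool = False,
    defaults: bool = False,
) -> tuple[np.ndarray, list[str]]:
    parts = term.split(":")
    block, names = _encode_single(parts[0], rows, baselines, levels,
                                  intercept_free, strict, defaults)
    for part in parts[1:]:
        b2, n2 = _encode_single(part, rows, baselines, levels,
                                intercept_free, strict, defaults)
        block = np.einsum("ni,nj->nij", block, b2).reshape(len(rows), -1)
        names = [f"{a}:{b}" for a in names for b in n2]
    return block, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] == 0:
        raise ConfoundingError("empty fixed design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns through pivoted QR
        _, r, piv = _qr_pivoted(X)
        tol = abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps if r.size else 0.0
        bad = [names[piv[i]] for i in range(X.shape[1])
               if i >= min(X.shape) or abs(r[i, i]) <= tol]
        raise ConfoundingError(
            f"fixed design is rank deficient; aliased column(s): {bad}"
        )


def _qr_pivoted(X: np.ndarray):
    import scipy.linalg

    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    return q, r, piv


def build_design(samples: pd.DataFrame, spec: DesignSpec) -> Design:
    """Build fixed, variability and group-level design structures.

    Raises :class:`ConfoundingError` when fixed columns are linearly
    dependent (complete confounding), naming the aliased terms.
    """
    sample_attrs = dict(getattr(samples, "attrs", {}))
    samples = samples.reset_index(drop=True)
    baselines = dict(spec.baselines)
    levels: dict[str, list[str]] = {}

    blocks, names, term_columns = [], [], {}
    for term in spec.fixed_terms:
        block, bnames = _encode_term(term, samples, baselines, levels,
                                     spec.intercept_free)
        start = sum(b.shape[1] for b in blocks)
        term_columns[term] = list(range(start, start + block.shape[1]))
        blocks.append(block)
        names.extend(bnames)
    X = np.column_stack(blocks) if blocks else np.zeros((len(samples), 0))
    _check_full_rank(X, names)

    vblocks, vnames = [], []
    for term in spec.variability_terms:
        block, bnames = _encode_term(term, samples, baselines, levels,
                                     spec.intercept_free)
        vblocks.append(block)
        vnames.extend(bnames)
    Xv = np.column_stack(vblocks) if vblocks else np.ones((len(samples), 1))
    if not vblocks:
        vnames = ["intercept"]

    groups: dict[str, GroupDesign] = {}
    for gname, slope_terms in spec.random_terms:
        if gname not in samples.columns:
            raise KeyError(f"grouping column {gname!r} not in sample table")
        gvals = samples[gname].astype(str)
        glevels = sorted(pd.unique(gvals))
        gindex = pd.Categorical(gvals, categories=glevels).codes.astype(int)
        sblocks, snames = [], []
        for term in slope_terms:
            block, bnames = _encode_term(term, samples, baselines, levels,
                                         spec.intercept_free)
            sblocks.append(block)
            snames.extend(bnames)
        slopes = np.column_stack(sblocks)
        groups[gname] = GroupDesign(gname, glevels, snames, gindex, slopes)

    sample_ids = (
        samples["sample_id"].astype(str).tolist()
        if "sample_id" in samples.columns
        else [str(i) for i in range(len(samples))]
    )
    ranges = {
        c: (float(samples[c].min()), float(samples[c].max()))
        for c in samples.columns
        if pd.api.types.is_numeric_dtype(samples[c]) and c not in levels
        and samples[c].notna().any()
    }
    return Design(
        X=X, x_names=names, Xv=Xv, xv_names=vnames, groups=groups,
        term_columns=term_columns, sample_ids=sample_ids, levels=levels,
        metadata={"baselines": baselines, "intercept_free": spec.intercept_free,
                  "spec": spec, "ranges": ranges,
                  **{k: v for k, v in sample_attrs.items()
                     if k in ("age_mean_days", "age_sd_days")}},
    )
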