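"""Metadata harmonisation, consensus annotation and cohort construction.

Raw atlas metadata is heterogeneous: ages arrive as numbers with units or as
developmental-stage strings, tissue labels follow study-specific vocabulary,
and each cell can carry up to four independent cell-type annotations (the
original study label plus reference-based re-annotations). This module
standardises all of that and applies the documented filtering rules that turn
an atlas into an analysis-ready cohort.

Consensus confidence tiers: tier 1 — all sources agree; tier 2/3 — one/two
sources disagree; tier 4 — no two sources agree, in which case the cell is
labelled ``"other immune"``. Tier-4 cells participate in compositional
modelling but are never tested for changes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CompositionMatrix

DAYS_PER_YEAR = 365.0

OTHER_IMMUNE = "other immune"

#: editable developmental-stage -> years fixture
DEFAULT_STAGE_YEARS: dict[str, float] = {
    "embryonic": 0.5 / DAYS_PER_YEAR * 100,   # ~50 days post conception
    "fetal": 0.5,
    "newborn": 0.0,
    "infant": 1.0,
    "child": 8.0,
    "adolescent": 15.0,
    "adult": 35.0,
    "middle aged": 50.0,
    "aged": 70.0,
}

#: tissues excluded from the non-lymphoid cellularity analyses
DEFAULT_LYMPHOID_TISSUES = frozenset(
    {"blood", "lymph node", "spleen", "thymus", "bone marrow"})

DEFAULT_EXCLUDED_CELL_TYPES = frozenset({"erythrocyte", "platelet"})

#: raw ethnicity labels merged to grow per-group sample size
DEFAULT_ETHNICITY_MERGE = {"Asian": "Asian", "Chinese": "Asian"}

CELL_CULTURE_SENTINEL = "cell culture"


class MappingError(KeyError):
    """An input label has no entry in the relevant ontology map."""


class InsufficientEvidenceError(ValueError):
    """Fewer than two non-missing annotation sources."""


class EmptyCohortError(RuntimeError):
    """All samples were excluded; carries the per-rule attrition table."""

    def __init__(self, attrition: pd.DataFrame):
        super().__init__(
            "no samples survive cohort filtering; attrition:\n"
            + attrition.to_string(index=False))
        self.attrition = attrition


# ---------------------------------------------------------------------------
# elementary harmonisers
# ---------------------------------------------------------------------------

def age_to_days(value, stage_map: dict[str, float] | None = None,
                unit: str = "days") -> float:
    """Convert an age to days.

    ``value`` is numeric (interpreted per ``unit``: "days" or "years") or a
    developmental-stage string looked up in ``stage_map`` (years, converted
    at 365 days/year exactly; e.g. the adolescent stage is 15 years = 5475
    days).
    """
    stage_map = DEFAULT_STAGE_YEARS if stage_map is None else stage_map
    if isinstance(value, str):
        key = value.strip().lower().removesuffix(" stage").strip()
        if key not in stage_map:
            raise MappingError(f"unknown developmental stage {value!r}")
        return float(stage_map[key]) * DAYS_PER_YEAR
    v = float(value)
    if unit == "days":
        return v
    if unit == "years":
        return v * DAYS_PER_YEAR
    raise ValueError(f"unknown age unit {unit!r}")


def harmonise_tissue(raw_label: str, tissue_map: dict[str, str]) -> str:
    """Map a raw tissue label to its harmonised class.

    Cell-culture labels should map to :data:`CELL_CULTURE_SENTINEL`, which
    downstream cohort construction excludes. Unmapped labels are an error —
    never a silent passthrough.
    """
    if not raw_label:
        raise ValueError("empty tissue label")
    if raw_label not in tissue_map:
        raise MappingError(f"tissue label {raw_label!r} has no harmonised class")
    return tissue_map[raw_label]


def build_sample_ids(cells: pd.DataFrame,
                     components: tuple[str, ...] = (
                         "dataset_id", "donor_id", "tissue_raw", "age_days", "sex"),
                     ) -> pd.DataFrame:
    """Resolve sample identifiers deterministically from metadata.

    Two cells share a ``sample_id`` iff all identifier components match, so
    cells grouped under one raw identifier but sourced from multiple tissues
    or donors of distinct ages are split into separate samples.
    """
    if "dataset_id" not in cells.columns:
        raise MappingError("cells lack a dataset_id column")
    cells = cells.copy()
    parts = []
    for comp in components:
        if comp in cells.columns:
            col = cells[comp]
            if pd.api.types.is_float_dtype(col):
                col = col.map(lambda v: f"{v:.6g}")
            parts.append(col.astype(str))
    joined = parts[0]
    for p in parts[1:]:
        joined = joined + "·" + p
    cells["sample_id"] = joined
    return cells


# ---------------------------------------------------------------------------
# consensus annotation
# ---------------------------------------------------------------------------

def consensus_annotation(labels, priority: tuple[int, ...] = (0, 1, 2, 3)
                         ) -> tuple[str, int]:
    """Modal label and confidence tier over up to four annotation sources.

    The tier is 1 plus the number of non-missing sources that disagree with
    the consensus. When no label reaches multiplicity 2 the cell gets
    ``("other immune", 4)``. Ties (e.g. 2-2) are broken by fixed source
    priority, original study annotation first.
    """
    observed = [(i, l) for i, l in enumerate(labels)
                if l is not None and not (isinstance(l, float) and np.isnan(l))]
    if len(observed) < 2:
        raise InsufficientEvidenceError(
            f"need >= 2 non-missing labels, got {len(observed)}")
    counts = Counter(l for _, l in observed)
    top = max(counts.values())
    if top == 1:
        return OTHER_IMMUNE, 4
    tied = [l for l, c in counts.items() if c == top]
    if len(tied) == 1:
        winner = tied[0]
    else:
        rank = {i: r for r, i in enumerate(priority)}
        best = {l: min(rank[i] for i, li in observed if li == l) for l in tied}
        winner = min(tied, key=lambda l: best[l])
    disagreements = sum(1 for _, l in observed if l != winner)
    return winner, 1 + disagreements


def annotate_cells(cells: pd.DataFrame,
                   source_columns: tuple[str, ...] = (
                       "label_source_1", "label_source_2",
                       "label_source_3", "label_source_4")) -> pd.DataFrame:
    """Apply :func:`consensus_annotation` row-wise; vectorised over patterns."""
    labs = cells[list(source_columns)]
    keys = labs.fillna("\0").agg(tuple, axis=1)
    cache: dict[tuple, tuple[str, int]] = {}
    consensus, tier = [], []
    for key in keys:
        if key not in cache:
            cache[key] = consensus_annotation(
                [None if l == "\0" else l for l in key])
        c, t = cache[key]
        consensus.append(c)
        tier.append(t)
    out = cells.copy()
    out["consensus_label"] = consensus
    out["confidence_tier"] = tier
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_counts(cells: pd.DataFrame, by: str = "consensus_label",
                     non_immune_labels: frozenset[str] = frozenset({"non_immune"}),
                     ) -> CompositionMatrix:
    """Per-sample integer counts over categories.

    ``by="consensus_label"`` (or any label column) yields the composition
    matrix; ``by="cellularity"`` yields the two-category immune/non-immune
    matrix derived from the ``is_immune`` column.
    """
    if by == "cellularity":
        if "is_immune" not in cells.columns:
            cells = cells.assign(
                is_immune=~cells["consensus_label"].isin(non_immune_labels))
        tab = pd.crosstab(cells["sample_id"],
                          np.where(cells["is_immune"], "immune", "non_immune"))
        for col in ("immune", "non_immune"):
            if col not in tab.columns:
                tab[col] = 0
        tab = tab[["immune", "non_immune"]]
    else:
        if by not in cells.columns:
            raise MappingError(f"cells lack a {by!r} column required for "
                               "aggregation")
        if cells[by].isna().any():
            raise MappingError(f"cells with missing {by!r} cannot be aggregated")
        tab = pd.crosstab(cells["sample_id"], cells[by])
        tab = tab[sorted(tab.columns)]
    tab.index = tab.index.astype(str)
    tab.columns = [str(c) for c in tab.columns]
    return CompositionMatrix(tab.sort_index())


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

@dataclass
class CohortThresholds:
    """All cohort-filter knobs with their documented defaults."""

    min_cells_per_sample: int = 30
    excluded_cell_types: frozenset = DEFAULT_EXCLUDED_CELL_TYPES
    ethnicity_merge: dict = field(default_factory=lambda: dict(DEFAULT_ETHNICITY_MERGE))
    min_age_days: float = DAYS_PER_YEAR            # 1 year post conception
    min_age_days_sex: float = 15 * DAYS_PER_YEAR   # sex contrasts: >= 15 y
    min_samples_per_ethnicity: int = 100
    lymphoid_tissues: frozenset = DEFAULT_LYMPHOID_TISSUES
    max_observed_cellularity: float = 0.75
    min_samples_per_dataset: int = 3
    composition_tiers: tuple[int, ...] = (1, 2, 3)
    collapse_10x: bool = True


ANALYSES = ("age", "sex", "ethnicity", "tissue_landscape")
MODES = ("cellularity", "composition")


def build_cohort(
    cells: pd.DataFrame,
    samples: pd.DataFrame,
    analysis: str = "age",
    mode: str = "composition",
    thresholds: CohortThresholds | None = None,
) -> tuple[CompositionMatrix, pd.DataFrame, pd.DataFrame]:
    """Apply the per-analysis filtering rules, in order, with attrition logging.

    Returns ``(counts, design_table, attrition)``. Every excluded sample is
    attributed to the first rule that triggers on it; the attrition table
    records samples (and cells) removed at each rule. Raises
    :class:`EmptyCohortError` when nothing survives.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"analysis must be one of {ANALYSES}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    th = thresholds or CohortThresholds()

    cells = cells.copy()
    samples = samples.copy().set_index("sample_id", drop=False)
    attrition: list[dict] = []

    def log_rule(rule: str, dropped_samples: int, dropped_cells: int = 0) -> None:
        attrition.append({"rule": rule, "samples_excluded": int(dropped_samples),
                          "cells_excluded": int(dropped_cells),
                          "samples_remaining": int(samples.shape[0])})

    def drop_samples(keep_mask: pd.Series, rule: str) -> None:
        nonlocal cells, samples
        dropped = int((~keep_mask).sum())
        samples = samples[keep_mask]
        cells = cells[cells["sample_id"].isin(samples.index)]
        log_rule(rule, dropped)

    # (1) primary, physiological samples only
    drop_samples(samples["is_primary"].astype(bool)
                 & samples["is_healthy"].astype(bool),
                 "primary_physiological")

    # (2) samples with fewer than 30 cells
    n_per = cells.groupby("sample_id").size()
    n_cells = samples.index.map(n_per).fillna(0).astype(int)
    drop_samples(pd.Series(n_cells >= th.min_cells_per_sample,
                           index=samples.index),
                 f"min_{th.min_cells_per_sample}_cells")

    # (3) erythrocytes and platelets out
    label_col = "consensus_label" if "consensus_label" in cells.columns else "true_label"
    bad = cells[label_col].isin(th.excluded_cell_types)
    cells = cells[~bad]
    log_rule("drop_erythrocytes_platelets", 0, int(bad.sum()))

    # (4) merge Asian descendants
    samples["ethnicity"] = samples["ethnicity"].replace(th.ethnicity_merge)

    if analysis == "age":
        # (5) unknown ages and samples < 1 year post conception
        known = samples["age_days"].notna()
        drop_samples(known & (samples["age_days"] >= th.min_age_days),
                     "age_known_and_postembryonic")
    if analysis == "sex":
        # (6) unknown sex, single-sex tissues, samples < 15 years
        drop_samples(samples["sex"].isin(["female", "male"]), "sex_known")
        both = samples.groupby("tissue_harmonised")["sex"].nunique()
        drop_samples(samples["tissue_harmonised"].map(both).ge(2),
                     "tissue_in_both_sexes")
        drop_samples(samples["age_days"].fillna(np.inf) >= th.min_age_days_sex,
                     "age_at_least_15y")
    if analysis == "ethnicity":
        # (7) unknown ethnicity; rare ethnicities -> "other"
        drop_samples(samples["ethnicity"].notna()
                     & ~samples["ethnicity"].isin(["unknown", "admixed"]),
                     "ethnicity_known")
        sizes = samples["ethnicity"].value_counts()
        rare = sizes[sizes < th.min_samples_per_ethnicity].index
        samples.loc[samples["ethnicity"].isin(rare), "ethnicity"] = "other"

    if mode == "cellularity":
        # (8) non-blood, non-lymphoid tissues; plausible observed cellularity
        if "is_immune" not in cells.columns:
            raise MappingError("cellularity mode needs an is_immune cell column")
        drop_samples(~samples["tissue_harmonised"].isin(th.lymphoid_tissues),
                     "non_lymphoid_tissue")
        imm = cells.groupby("sample_id")["is_immune"].agg(["sum", "size"])
        observed = (imm["sum"] / imm["size"]).reindex(samples.index).fillna(0.0)
        samples["observed_cellularity"] = observed
        drop_samples(observed <= th.max_observed_cellularity,
                     f"cellularity_at_most_{th.max_observed_cellularity}")
        n_immune = imm["sum"].reindex(samples.index).fillna(0)
        drop_samples(n_immune >= 1, "at_least_one_immune_cell")
        per_dataset = samples.groupby("dataset_id").size()
        drop_samples(samples["dataset_id"].map(per_dataset)
                     .ge(th.min_samples_per_dataset),
                     f"dataset_min_{th.min_samples_per_dataset}_samples")
    else:
        # (9) immune cells with confidence tiers 1-3 only
        if "confidence_tier" not in cells.columns:
            cells = annotate_cells(cells)
        imm_mask = cells["is_immune"].astype(bool) if "is_immune" in cells.columns \
            else pd.Series(True, index=cells.index)
        tier_mask = cells["confidence_tier"].isin(th.composition_tiers)
        dropped_cells = int((~(imm_mask & tier_mask)).sum())
        cells = cells[imm_mask & tier_mask]
        log_rule("immune_tier_1_to_3_cells", 0, dropped_cells)
        per_dataset = samples.groupby("dataset_id").size()
        drop_samples(samples["dataset_id"].map(per_dataset)
                     .ge(th.min_samples_per_dataset),
                     f"dataset_min_{th.min_samples_per_dataset}_samples")

    # (10) collapse 10X chemistry variants when technology is not of interest
    if th.collapse_10x and "assay" in samples.columns:
        is_10x = samples["assay"].astype(str).str.lower().str.startswith("10x")
        samples.loc[is_10x, "assay"] = "10x"

    attrition_df = pd.DataFrame(attrition)
    if samples.empty:
        raise EmptyCohortError(attrition_df)

    # age scaling on the retained cohort (z-score; mean 0, unit variance)
    known_age = samples["age_days"].astype(float)
    mu = float(known_age.mean())
    sd = float(known_age.std(ddof=0))
    samples["age_scaled"] = 0.0 if sd == 0 or np.isnan(sd) else (known_age - mu) / sd
    samples["age_scaled"] = samples["age_scaled"].fillna(0.0)
    samples.attrs["age_mean_days"] = mu
    samples.attrs["age_sd_days"] = sd if sd else 1.0

    if mode == "cellularity":
        counts = aggregate_counts(cells, by="cellularity")
    else:
        label_col = "consensus_label" if "consensus_label" in cells.columns else "true_label"
        counts = aggregate_counts(cells, by=label_col)
    counts = CompositionMatrix(
        counts.counts.reindex(sorted(samples.index)).fillna(0).astype(int))
    design_table = samples.loc[sorted(samples.index)].reset_index(drop=True)
    design_table.attrs = dict(samples.attrs)
    return counts, design_table, attrition_df
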