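"""Metadata harmonisation, consensus tiers, and cohort filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlascomp import harmonise as hz
from atlascomp.harmonise import (CohortThresholds, EmptyCohortError,
                                 InsufficientEvidenceError, MappingError,
                                 OTHER_IMMUNE, age_to_days, aggregate_counts,
                                 annotate_cells, build_cohort,
                                 build_sample_ids, consensus_annotation,
                                 harmonise_tissue)


class TestAgeToDays:
    def test_adolescent_stage_is_5475_days(self):
        assert age_to_days("adolescent") == 5475.0

    def test_year_unit_conversion(self):
        assert age_to_days(1, unit="years") == 365.0

    def test_days_pass_through(self):
        assert age_to_days(730) == 730.0

    def test_stage_suffix_tolerated(self):
        assert age_to_days("adolescent stage") == 5475.0

    def test_unknown_stage_raises_with_name(self):
        with pytest.raises(MappingError, match="mesozoic"):
            age_to_days("mesozoic")


class TestTissueMap:
    def test_direct_lookup(self):
        assert harmonise_tissue("left cardiac atrium",
                                {"left cardiac atrium": "heart"}) == "heart"

    def test_unmapped_label_raises_with_name(self):
        with pytest.raises(MappingError, match="xenon chamber"):
            harmonise_tissue("xenon chamber", {"lung": "lung"})

    def test_identity_map(self):
        assert harmonise_tissue("lung", {"lung": "lung"}) == "lung"


class TestSampleIds:
    def test_one_raw_id_split_across_tissues(self):
        cells = pd.DataFrame({
            "dataset_id": ["d1"] * 4,
            "donor_id": ["x"] * 4,
            "tissue_raw": ["lung", "lung", "heart", "heart"],
            "age_days": [100.0] * 4,
            "sex": ["female"] * 4,
        })
        out = build_sample_ids(cells)
        assert out["sample_id"].nunique() == 2

    def test_identical_metadata_single_sample(self):
        cells = pd.DataFrame({"dataset_id": ["d"] * 3, "donor_id": ["x"] * 3,
                              "tissue_raw": ["lung"] * 3,
                              "age_days": [1.0] * 3, "sex": ["male"] * 3})
        assert build_sample_ids(cells)["sample_id"].nunique() == 1

    def test_idempotent(self):
        cells = pd.DataFrame({"dataset_id": ["d"] * 2, "donor_id": ["x", "y"],
                              "tissue_raw": ["lung"] * 2,
                              "age_days": [1.0, 2.0], "sex": ["male"] * 2})
        once = build_sample_ids(cells)
        twice = build_sample_ids(once)
        pd.testing.assert_series_equal(once["sample_id"], twice["sample_id"])

    def test_missing_dataset_id_raises(self):
        with pytest.raises(MappingError):
            build_sample_ids(pd.DataFrame({"donor_id": ["x"]}))


def voting_oracle(labels, priority=(0, 1, 2, 3)):
    """Independent brute-force vote: per candidate count supporters; the
    winner maximises (count, earliest priority supporter); no candidate with
    two supporters means no consensus."""
    observed = [(i, l) for i, l in enumerate(labels) if l is not None]
    best = None
    for cand in {l for _, l in observed}:
        supporters = [priority.index(i) for i, l in observed if l == cand]
        key = (len(supporters), -min(supporters))
        if best is None or key > best[0]:
            best = (key, cand)
    if best[0][0] < 2:
        return OTHER_IMMUNE, 4
    winner = best[1]
    return winner, 1 + sum(1 for _, l in observed if l != winner)


ALPHABET = ["T", "B", "NK", "mono", "DC"]


def test_consensus_matches_oracle_on_full_enumeration():
    for labels in itertools.product(ALPHABET, repeat=4):
        assert consensus_annotation(labels) == voting_oracle(labels), labels


@settings(max_examples=300, derandomize=True)
@given(st.lists(st.sampled_from(ALPHABET + [None]), min_size=2, max_size=4))
def test_consensus_matches_oracle_with_missing_sources(labels):
    labels = labels + [None] * (4 - len(labels))
    if sum(l is not None for l in labels) < 2:
        with pytest.raises(InsufficientEvidenceError):
            consensus_annotation(labels)
    else:
        assert consensus_annotation(labels) == voting_oracle(labels)


class TestConsensusExamples:
    @pytest.mark.parametrize("labels,expected", [
        (("T", "T", "T", "T"), ("T", 1)),
        (("T", "T", "T", "B"), ("T", 2)),
        (("T", "T", "B", "NK"), ("T", 3)),
        (("T", "B", "NK", "mono"), (OTHER_IMMUNE, 4)),
        # 2-2 tie resolved by source priority: original study label wins
        (("T", "T", "B", "B"), ("T", 3)),
        (("B", "B", "T", "T"), ("B", 3)),
    ])
    def test_tier_rules(self, labels, expected):
        assert consensus_annotation(labels) == expected

    def test_fewer_than_two_sources_rejected(self):
        with pytest.raises(InsufficientEvidenceError):
            consensus_annotation(("T", None, None, None))


class TestAggregateCounts:
    def test_simple_aggregation(self):
        cells = pd.DataFrame({"sample_id": ["s1"] * 3,
                              "consensus_label": ["T", "T", "B"]})
        mat = aggregate_counts(cells)
        assert mat.counts.loc["s1", "T"] == 2
        assert mat.counts.loc["s1", "B"] == 1

    def test_cellularity_two_categories(self):
        cells = pd.DataFrame({"sample_id": ["s1"] * 10,
                              "is_immune": [True] * 4 + [False] * 6})
        mat = aggregate_counts(cells, by="cellularity")
        assert mat.categories == ["immune", "non_immune"]
        assert mat.counts.loc["s1"].tolist() == [4, 6]

    def test_column_order_sorted_and_stable(self):
        cells = pd.DataFrame({"sample_id": ["s1", "s1", "s2"],
                              "consensus_label": ["b", "a", "a"]})
        assert aggregate_counts(cells).categories == ["a", "b"]

    def test_missing_labels_rejected(self):
        cells = pd.DataFrame({"sample_id": ["s1"],
                              "consensus_label": [np.nan]})
        with pytest.raises(MappingError):
            aggregate_counts(cells)


class TestBuildCohort:
    def test_small_sample_excluded_at_min_cells_rule(self, toy_cells_and_samples):
        cells, samples = toy_cells_and_samples
        counts, table, attrition = build_cohort(
            annotate_cells(cells), samples, analysis="age", mode="composition")
        assert "s_small" not in table["sample_id"].tolist()
        row = attrition.set_index("rule").loc["min_30_cells"]
        assert row["samples_excluded"] == 1

    def test_unhealthy_sample_excluded_first(self, toy_cells_and_samples):
        cells, samples = toy_cells_and_samples
        _, table, attrition = build_cohort(
            annotate_cells(cells), samples, analysis="age", mode="composition")
        assert "s_sick" not in table["sample_id"].tolist()
        assert attrition.set_index("rule").loc["primary_physiological",
                                               "samples_excluded"] == 1

    def test_high_cellularity_sample_excluded_in_cellularity_mode(
            self, toy_cells_and_samples):
        cells, samples = toy_cells_and_samples
        _, table, attrition = build_cohort(
            annotate_cells(cells), samples, analysis="age", mode="cellularity")
        assert "s_dense" not in table["sample_id"].tolist()
        assert attrition.set_index("rule").loc["cellularity_at_most_0.75",
                                               "samples_excluded"] == 1

    def test_all_passing_cohort_has_zero_exclusions(self):
        samples = pd.DataFrame([
            dict(sample_id=f"s{i}", dataset_id="d1", tissue_harmonised="lung",
                 age_days=40 * 365.0 + i, sex="female", ethnicity="European",
                 assay="10x", is_primary=True, is_healthy=True)
            for i in range(5)])
        cells = pd.DataFrame([
            dict(cell_id=f"s{i}_c{j}", sample_id=f"s{i}",
                 label_source_1="T", label_source_2="T",
                 label_source_3="T", label_source_4="T", is_immune=True)
            for i in range(5) for j in range(40)])
        _, table, attrition = build_cohort(
            annotate_cells(cells), samples, analysis="age", mode="composition")
        assert (attrition["samples_excluded"] == 0).all()
        assert len(table) == 5

    def test_age_scaling_zero_mean_unit_variance(self, toy_cells_and_samples):
        cells, samples = toy_cells_and_samples
        samples = samples.copy()
        samples["age_days"] = np.linspace(10, 70, len(samples)) * 365.0
        _, table, _ = build_cohort(annotate_cells(cells), samples,
                                   analysis="age", mode="composition")
        assert abs(table["age_scaled"].mean()) < 1e-9
        assert abs(table["age_scaled"].std(ddof=0) - 1.0) < 1e-9

    def test_idempotent_on_clean_cohort(self, toy_cells_and_samples):
        cells, samples = toy_cells_and_samples
        cells = annotate_cells(cells)
        counts1, table1, _ = build_cohort(cells, samples, "age", "composition")
        counts2, table2, _ = build_cohort(
            cells[cells["sample_id"].isin(table1["sample_id"])],
            table1, "age", "composition")
        pd.testing.assert_frame_equal(counts1.counts, counts2.counts)

    def test_erythrocytes_and_platelets_dropped(self):
        samples = pd.DataFrame([
            dict(sample_id="s1", dataset_id="d1", tissue_harmonised="lung",
                 age_days=365.0 * 30, sex="female", ethnicity="European",
                 assay="10x", is_primary=True, is_healthy=True)])
        cells = pd.DataFrame(
            [dict(cell_id=f"c{j}", sample_id="s1", label_source_1="T",
                  label_source_2="T", label_source_3="T", label_source_4="T",
                  is_immune=True) for j in range(35)]
            + [dict(cell_id="e1", sample_id="s1", label_source_1="erythrocyte",
                    label_source_2="erythrocyte", label_source_3="erythrocyte",
                    label_source_4="erythrocyte", is_immune=False)])
        counts, _, attrition = build_cohort(
            annotate_cells(cells), samples, "age", "composition",
            CohortThresholds(min_samples_per_dataset=1))
        assert "erythrocyte" not in counts.categories
        assert attrition.set_index("rule").loc["drop_erythrocytes_platelets",
                                               "cells_excluded"] == 1

    def test_tier4_cells_kept_in_composition(self):
        samples = pd.DataFrame([
            dict(sample_id="s1", dataset_id="d1", tissue_harmonised="lung",
                 age_days=365.0 * 30, sex="female", ethnicity="European",
                 assay="10x", is_primary=True, is_healthy=True)])
        cells = pd.DataFrame(
            [dict(cell_id=f"c{j}", sample_id="s1", label_source_1="T",
                  label_source_2="T", label_source_3="T", label_source_4="T",
                  is_immune=True) for j in range(35)]
            + [dict(cell_id="t4", sample_id="s1", label_source_1="T",
                    label_source_2="B", label_source_3="NK",
                    label_source_4="mono", is_immune=True)])
        # default high-confidence filter keeps tiers 1-3 only
        counts, _, _ = build_cohort(annotate_cells(cells), samples,
                                    "age", "composition",
                                    CohortThresholds(min_samples_per_dataset=1))
        assert OTHER_IMMUNE not in counts.categories
        # widening to tier 4 carries "other immune" as its own category,
        # which effect testing reports but never flags significant
        counts4, _, _ = build_cohort(
            annotate_cells(cells), samples, "age", "composition",
            CohortThresholds(min_samples_per_dataset=1,
                             composition_tiers=(1, 2, 3, 4)))
        assert OTHER_IMMUNE in counts4.categories

    def test_ten_x_variants_collapse(self, toy_cells_and_samples):
        cells, samples = toy_cells_and_samples
        _, table, _ = build_cohort(annotate_cells(cells), samples,
                                   "age", "composition")
        assert set(table["assay"]) == {"10x"}

    def test_empty_cohort_raises_with_attrition(self, toy_cells_and_samples):
        cells, samples = toy_cells_and_samples
        samples = samples.assign(is_healthy=False)
        with pytest.raises(EmptyCohortError) as err:
            build_cohort(annotate_cells(cells), samples, "age", "composition")
        assert err.value.attrition["samples_excluded"].sum() == len(samples)

    def test_every_exclusion_attributed_once(self, toy_cells_and_samples):
        cells, samples = toy_cells_and_samples
        _, table, attrition = build_cohort(annotate_cells(cells), samples,
                                           "age", "composition")
        assert (attrition["samples_excluded"].sum()
                == len(samples) - len(table))

    def test_asian_descendants_merged(self):
        samples = pd.DataFrame([
            dict(sample_id=f"s{i}", dataset_id="d1", tissue_harmonised="lung",
                 age_days=365.0 * 30, sex="female",
                 ethnicity=eth, assay="10x", is_primary=True, is_healthy=True)
            for i, eth in enumerate(["Chinese", "Asian", "European"])])
        cells = pd.DataFrame([
            dict(cell_id=f"s{i}_c{j}", sample_id=f"s{i}", label_source_1="T",
                 label_source_2="T", label_source_3="T", label_source_4="T",
                 is_immune=True)
            for i in range(3) for j in range(35)])
        _, table, _ = build_cohort(annotate_cells(cells), samples,
                                   "age", "composition")
        assert set(table["ethnicity"]) == {"Asian", "European"}
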