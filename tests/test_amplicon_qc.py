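import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pitfoam.amplicon_qc import (
    OtuTable,
    aggregate_taxonomy,
    filter_rare_otus,
    filter_samples,
    goods_coverage,
    relative_abundance,
    sample_coverage,
)


class TestGoodsCoverage:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 3, 2), 1.0),  # no singletons
            ((1, 9), 0.9),  # one singleton in ten reads
            (tuple([1] * 100), 0.0),  # everything a singleton
            ((0, 4, 1, 1), 1.0 - 2 / 6),
        ],
    )
    def test_values(self, counts, expected):
        assert goods_coverage(counts) == pytest.approx(expected)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            goods_coverage([0, 0, 0])

    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=40))
    def test_permutation_invariant(self, counts):
        if sum(counts) == 0:
            return
        shuffled = sorted(counts, reverse=True)
        assert goods_coverage(counts) == pytest.approx(goods_coverage(shuffled))


class TestFilterRareOtus:
    def test_threshold_is_inclusive(self):
        # row sums: 10, 4, 5, 0 -> retain the >=5 rows only
        counts = pd.DataFrame(
            {"a": [5, 2, 5, 0], "b": [3, 1, 0, 0], "c": [2, 1, 0, 0]},
            index=["o1", "o2", "o3", "o4"],
        )
        out, report = filter_rare_otus(OtuTable(counts), min_total=5)
        assert out.otu_ids == ["o1", "o3"]
        assert set(report.removed_otus) == {"o2", "o4"}
        assert out.sample_ids == ["a", "b", "c"]

    def test_min_total_one_is_identity_without_zero_rows(self, toy_table):
        out, _ = filter_rare_otus(toy_table, min_total=1)
        # otuD is an all-zero row, the only removal at threshold 1
        assert out.otu_ids == ["otuA", "otuB", "otuC"]

    def test_invalid_threshold(self, toy_table):
        with pytest.raises(ValueError):
            filter_rare_otus(toy_table, min_total=0)

    def test_idempotent(self, small_cohort):
        table = small_cohort[0]
        once, _ = filter_rare_otus(table)
        twice, rep = filter_rare_otus(once)
        assert twice.otu_ids == once.otu_ids
        assert not rep.removed_otus


class TestFilterSamples:
    def test_every_sample_passing_is_identity(self, toy_table):
        out, report = filter_samples(toy_table, min_reads=1, min_coverage=0.0)
        assert out.sample_ids == toy_table.sample_ids
        assert not report.removed_samples

    def test_depth_and_coverage_reasons(self):
        # s1: depth 9, no singletons; s2: depth 10, coverage 0.8
        counts = pd.DataFrame(
            {"s1": [4, 5, 0, 0], "s2": [6, 2, 1, 1]}, index=list("wxyz")
        )
        out, report = filter_samples(OtuTable(counts), min_reads=10, min_coverage=0.9)
        assert out.sample_ids == []
        assert "depth" in report.removed_samples["s1"]
        assert "coverage" in report.removed_samples["s2"]

    def test_partition_is_exact(self, small_cohort):
        table = small_cohort[0]
        out, report = filter_samples(table, 10_000, 0.97)
        assert set(out.sample_ids) | set(report.removed_samples) == set(
            table.sample_ids
        )
        assert not set(out.sample_ids) & set(report.removed_samples)


class TestRelativeAbundance:
    def test_columns_sum_to_one(self, small_cohort):
        table = small_cohort[0]
        rel = relative_abundance(table)
        np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "column, expected",
        [([2, 2], [0.5, 0.5]), ([3, 1, 0], [0.75, 0.25, 0.0]), ([7], [1.0])],
    )
    def test_simple_columns(self, column, expected):
        table = OtuTable(pd.DataFrame({"s": column}))
        np.testing.assert_allclose(relative_abundance(table)["s"], expected)

    def test_zero_depth_is_error(self):
        table = OtuTable(pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}))
        with pytest.raises(ValueError):
            relative_abundance(table)


class TestAggregateTaxonomy:
    def test_same_genus_merges_and_conserves_totals(self, toy_table):
        agg = aggregate_taxonomy(toy_table, "genus")
        assert set(agg.otu_ids) == {"Sporobacter", "unclassified Clostridia", "unclassified Bacteria"}
        # conservation of per-sample totals
        np.testing.assert_array_equal(
            agg.counts.sum(axis=0), toy_table.counts.sum(axis=0)
        )
        # otuA + otuB share the genus
        np.testing.assert_array_equal(
            agg.counts.loc["Sporobacter"],
            toy_table.counts.loc["otuA"] + toy_table.counts.loc["otuB"],
        )

    def test_unclassified_pooled_by_parent(self):
        counts = pd.DataFrame({"s": [1, 2, 4]}, index=["a", "b", "c"])
        tax = {
            "a": "k__Bacteria;p__Firmicutes;c__Clostridia;o__x;f__y;g__A;s__",
            "b": "k__Bacteria;p__Firmicutes;c__Clostridia;o__x;f__y;g__A;s__",
            "c": "k__Bacteria;p__Firmicutes;c__Clostridia;o__x;f__y;g__;s__",
        }
        agg = aggregate_taxonomy(OtuTable(counts, tax), "genus")
        assert agg.counts.loc["A", "s"] == 3
        assert agg.counts.loc["unclassified y", "s"] == 4

    def test_distinct_taxa_keep_row_count(self):
        counts = pd.DataFrame({"s": [1, 2]}, index=["a", "b"])
        tax = {
            "a": "k__Bacteria;p__P1",
            "b": "k__Bacteria;p__P2",
        }
        agg = aggregate_taxonomy(OtuTable(counts, tax), "phylum")
        assert agg.n_otus == 2

    def test_unknown_rank(self, toy_table):
        with pytest.raises(ValueError):
            aggregate_taxonomy(toy_table, "strain")


class TestOtuTableIO:
    def test_tsv_round_trip(self, toy_table, tmp_path):
        toy_table.to_tsv(tmp_path / "c.tsv", tmp_path / "t.tsv")
        back = OtuTable.from_tsv(tmp_path / "c.tsv", tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)
        assert back.taxonomy == toy_table.taxonomy

    def test_rejects_negative_and_duplicate(self):
        with pytest.raises(ValueError):
            OtuTable(pd.DataFrame({"s": [-1, 2]}))
        dup = pd.DataFrame({"s": [1, 2]}, index=["x", "x"])
        with pytest.raises(ValueError):
            OtuTable(dup)

    def test_coverage_computed_per_sample(self, toy_table):
        cov = sample_coverage(toy_table)
        assert cov["s1"] == pytest.approx(1 - 1 / 9)
        assert cov["s3"] == pytest.approx(0.0)
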