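import numpy as np
import pandas as pd
import pytest

from pitfoam import amplicon_qc as qc
from pitfoam.core_community import (
    CoreSet,
    bootstrap_ci,
    core_taxa,
    diff_abundance_to_frame,
    differential_abundance,
    venn_partition,
)


@pytest.fixture()
def presence_table():
    counts = pd.DataFrame(
        {
            "s1": [3, 1, 0, 2],
            "s2": [2, 1, 1, 0],
            "s3": [4, 0, 2, 1],
            "s4": [1, 5, 1, 1],
            "s5": [2, 2, 3, 1],
        },
        index=["core_all", "gappy1", "gappy2", "gappy3"],
    )
    meta = pd.DataFrame(
        {"texture": ["foam"] * 5, "farm": ["f1"] * 5, "month": range(1, 6)},
        index=counts.columns,
    )
    return qc.OtuTable(counts), meta


class TestCoreTaxa:
    def test_full_prevalence_requires_all_samples(self, presence_table):
        table, meta = presence_table
        core = core_taxa(table, meta, "foam", prevalence=1.0)
        assert core.members == {"core_all"}

    def test_four_of_five_excluded_at_full_prevalence(self, presence_table):
        table, meta = presence_table
        core = core_taxa(table, meta, "foam", prevalence=1.0)
        assert "gappy1" not in core.members  # present in 4/5 samples

    def test_zero_prevalence_keeps_any_occurrence(self, presence_table):
        table, meta = presence_table
        core = core_taxa(table, meta, "foam", prevalence=0.0)
        assert core.members == set(table.otu_ids)

    def test_monotone_in_prevalence(self, presence_table):
        table, meta = presence_table
        lo = core_taxa(table, meta, "foam", prevalence=0.6).members
        hi = core_taxa(table, meta, "foam", prevalence=1.0).members
        assert hi <= lo

    def test_empty_group_is_error(self, presence_table):
        table, meta = presence_table
        with pytest.raises(ValueError):
            core_taxa(table, meta, "crust")


class TestVennPartition:
    def test_identical_sets_concentrate_in_center(self):
        cores = [CoreSet(g, {"a", "b", "c"}, 1.0) for g in ("x", "y", "z")]
        out = venn_partition(cores)
        assert out["x&y&z"] == 3
        assert sum(out.values()) == 3

    def test_disjoint_sets_only_unique_regions(self):
        cores = [
            CoreSet("x", {"a"}, 1.0),
            CoreSet("y", {"b"}, 1.0),
            CoreSet("z", {"c"}, 1.0),
        ]
        out = venn_partition(cores)
        assert out["x"] == out["y"] == out["z"] == 1
        assert out["x&y&z"] == 0

    def test_hand_enumerated_partition(self):
        cores = [
            CoreSet("x", {"a", "b", "c"}, 1.0),
            CoreSet("y", {"b", "c", "d"}, 1.0),
            CoreSet("z", {"c", "e"}, 1.0),
        ]
        out = venn_partition(cores)
        assert out == {
            "x": 1, "y": 1, "z": 1,
            "x&y": 1, "x&z": 0, "y&z": 0,
            "x&y&z": 1,
        }
        assert sum(out.values()) == 5  # union size

    def test_counts_sum_to_union(self, small_cohort):
        t16, _, meta, _ = small_cohort
        t1, _ = qc.filter_rare_otus(t16)
        cores = [
            core_taxa(t1, meta, tex, prevalence=0.8)
            for tex in ("no-foam", "crust", "foam")
        ]
        out = venn_partition(cores)
        union = set().union(*(c.members for c in cores))
        assert sum(out.values()) == len(union)
        assert all(v >= 0 for v in out.values())

    def test_fewer_than_two_sets_is_error(self):
        with pytest.raises(ValueError):
            venn_partition([CoreSet("x", set(), 1.0)])


class TestBootstrapCi:
    def test_constant_vector_collapses(self):
        lo, mean, hi = bootstrap_ci(np.full(10, 0.2), n_boot=99, seed=0)
        assert lo == mean == hi == pytest.approx(0.2)

    def test_deterministic_under_seed(self, rng):
        v = rng.normal(0.2, 0.05, 50)
        assert bootstrap_ci(v, seed=4) == bootstrap_ci(v, seed=4)

    def test_coverage_close_to_nominal(self):
        covered = 0
        n_sim = 300
        for seed in range(n_sim):
            r = np.random.default_rng(seed)
            v = r.normal(0.2, 0.05, 100)
            lo, _, hi = bootstrap_ci(v, n_boot=199, seed=seed)
            covered += lo <= 0.2 <= hi
        assert 0.91 <= covered / n_sim <= 0.985

    def test_ci_brackets_mean(self, rng):
        v = rng.normal(0, 1, 40)
        lo, mean, hi = bootstrap_ci(v, seed=0)
        assert lo <= mean <= hi

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0, 2.0, 3.0])


class TestDifferentialAbundance:
    def test_planted_enriched_taxon_flagged_with_correct_label(self, rng):
        n_per = 60
        groups = np.repeat(["no-foam", "crust", "foam"], n_per)
        meta = pd.DataFrame(
            {"texture": groups}, index=[f"s{i}" for i in range(3 * n_per)]
        )
        base = rng.dirichlet(np.ones(5), 3 * n_per).T * 0.8
        enriched = np.where(groups == "foam", 0.2, 0.02) + rng.normal(
            0, 0.005, 3 * n_per
        )
        rel = np.vstack([base, np.clip(enriched, 1e-4, None)])
        rel /= rel.sum(axis=0)
        frame = pd.DataFrame(
            rel, index=[f"t{i}" for i in range(5)] + ["enriched"], columns=meta.index
        )
        records = differential_abundance(
            frame, meta, rank="genus", n_boot=99, seed=0
        )
        rec = {r.taxon: r for r in records}["enriched"]
        assert rec.significant
        assert rec.most_abundant_in == "foam"
        for g, (lo, mean, hi) in rec.group_cis.items():
            assert lo <= mean <= hi

    def test_shuffled_labels_flag_nothing_decisive(self, small_cohort, rng):
        t16, _, meta, _ = small_cohort
        t1, _ = qc.filter_rare_otus(t16)
        agg = qc.aggregate_taxonomy(t1, "genus")
        rel = qc.relative_abundance(agg)
        shuffled = meta.copy()
        shuffled["texture"] = rng.permutation(meta["texture"].to_numpy())
        records = differential_abundance(
            rel, shuffled, rank="genus", n_boot=29, seed=0
        )
        assert sum(r.significant for r in records) <= 1

    def test_frame_export(self, rng):
        meta = pd.DataFrame(
            {"texture": np.repeat(["a", "b", "c"], 10)},
            index=[f"s{i}" for i in range(30)],
        )
        rel = pd.DataFrame(
            rng.dirichlet(np.ones(4), 30).T,
            index=list("wxyz"),
            columns=meta.index,
        )
        frame = diff_abundance_to_frame(
            differential_abundance(rel, meta, rank="species", n_boot=29, seed=1)
        )
        assert {"taxon", "rank", "BF10", "significant", "most_abundant_in"} <= set(
            frame.columns
        )
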