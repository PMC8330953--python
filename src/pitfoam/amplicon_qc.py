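"""OTU-table quality control and standardization.

Amplicon surveys (bacterial 16S rRNA and methanogen *mcrA* here) arrive as
integer count tables: OTUs (operational taxonomic units, 97%-identity
sequence clusters) by samples, plus a ranked taxonomic lineage per OTU.
Before any community statistics, two filters are applied:

* OTUs observed fewer than ``min_total`` times across *all* samples are
  dropped (spurious clusters, sequencing artifacts);
* samples with too few reads or too low Good's coverage are dropped
  (inadequately sequenced communities).

Good's coverage, ``1 - F1/N`` where ``F1`` is the number of singleton OTUs
in a sample and ``N`` its read total, estimates what fraction of the
community's individuals belong to already-observed OTUs.

Counts are never rarefied; downstream analyses consume raw counts or
per-sample relative abundances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "QcReport",
    "RANKS",
    "SAMPLE_FILTER_PRESETS",
    "goods_coverage",
    "sample_coverage",
    "filter_rare_otus",
    "filter_samples",
    "relative_abundance",
    "aggregate_taxonomy",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: (min_reads, min_coverage) per marker gene.
SAMPLE_FILTER_PRESETS = {"16s": (10_000, 0.97), "mcra": (4_000, 0.99)}


@dataclass
class OtuTable:
    """Integer OTU count matrix (OTUs x samples) with taxonomy lineages.

    ``counts`` is indexed by OTU id with sample ids as columns. ``taxonomy``
    maps OTU id to a semicolon-delimited ranked lineage such as
    ``"k__Bacteria;p__Firmicutes;c__Clostridia;o__;f__;g__;s__"``; OTUs may
    be absent from the map or unclassified at deeper ranks.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("OTU counts must be integral")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate OTU ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.counts.index.name = None
        self.counts.columns.name = None
        unknown = set(self.taxonomy) - set(self.counts.index)
        if unknown:
            raise ValueError(f"taxonomy keys not in table: {sorted(unknown)[:5]} ...")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample read totals."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "OtuTable":
        sub = self.counts.loc[:, list(sample_ids)]
        tax = {o: l for o, l in self.taxonomy.items()}
        return OtuTable(sub, tax)

    # -- TSV dialect: first column "otu_id", header row of sample ids -------

    def to_tsv(self, counts_path, taxonomy_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(counts_path, sep="\t")
        if taxonomy_path is not None:
            with open(taxonomy_path, "w") as fh:
                fh.write("otu_id\tlineage\n")
                for otu in self.otu_ids:
                    fh.write(f"{otu}\t{self.taxonomy.get(otu, '')}\n")

    @classmethod
    def from_tsv(cls, counts_path, taxonomy_path=None) -> "OtuTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        taxonomy: dict[str, str] = {}
        if taxonomy_path is not None and Path(taxonomy_path).exists():
            tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
            taxonomy = tax.iloc[:, 0].fillna("").to_dict()
            taxonomy = {k: v for k, v in taxonomy.items() if k in counts.index}
        return cls(counts, taxonomy)


@dataclass
class QcReport:
    """Record of one filtering step: what was removed and why."""

    step: str
    params: dict
    removed_otus: dict[str, str] = field(default_factory=dict)
    removed_samples: dict[str, str] = field(default_factory=dict)
    depths: dict[str, int] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "step": self.step,
                    "params": self.params,
                    "removed_otus": self.removed_otus,
                    "removed_samples": self.removed_samples,
                    "depths": self.depths,
                    "coverage": self.coverage,
                },
                fh,
                indent=1,
            )


def goods_coverage(counts) -> float:
    """Good's coverage ``1 - F1/N`` for a single sample's count vector.

    ``F1`` is the number of OTUs observed exactly once and ``N`` the total
    read count. Raises on an all-zero vector.
    """
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("Good's coverage undefined for an all-zero sample")
    singletons = int((arr == 1).sum())
    return 1.0 - singletons / float(total)


def sample_coverage(table: OtuTable) -> pd.Series:
    """Good's coverage for every sample of a table."""
    arr = table.counts.to_numpy()
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero samples: {bad}")
    f1 = (arr == 1).sum(axis=0)
    return pd.Series(1.0 - f1 / totals, index=table.counts.columns)


def filter_rare_otus(table: OtuTable, min_total: int = 5) -> tuple[OtuTable, QcReport]:
    """Drop OTUs with total count across all samples below ``min_total``.

    The default of 5 removes OTUs observed fewer than five times overall;
    the sample set is unchanged.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals >= min_total
    removed = {
        otu: f"total count {int(totals[otu])} < {min_total}"
        for otu in table.counts.index[~keep]
    }
    kept = table.counts.loc[keep]
    tax = {o: l for o, l in table.taxonomy.items() if o in kept.index}
    report = QcReport(
        step="filter_rare_otus", params={"min_total": min_total}, removed_otus=removed
    )
    return OtuTable(kept, tax), report


def filter_samples(
    table: OtuTable, min_reads: int, min_coverage: float
) -> tuple[OtuTable, QcReport]:
    """Drop samples failing the read-depth or Good's-coverage threshold.

    Presets: 16S uses (10000, 0.97); mcrA uses (4000, 0.99) — see
    :data:`SAMPLE_FILTER_PRESETS`. Coverage is computed on the table as
    given, i.e. after whatever OTU filtering preceded this call.
    """
    if min_reads < 0 or min_coverage < 0:
        raise ValueError("thresholds must be >= 0")
    depths = table.depths()
    coverage = sample_coverage(table)
    removed: dict[str, str] = {}
    for sample in table.sample_ids:
        reasons = []
        if depths[sample] < min_reads:
            reasons.append(f"depth {int(depths[sample])} < {min_reads}")
        if coverage[sample] < min_coverage:
            reasons.append(f"coverage {coverage[sample]:.4f} < {min_coverage}")
        if reasons:
            removed[sample] = "; ".join(reasons)
    keep = [s for s in table.sample_ids if s not in removed]
    report = QcReport(
        step="filter_samples",
        params={"min_reads": min_reads, "min_coverage": min_coverage},
        removed_samples=removed,
        depths={s: int(depths[s]) for s in table.sample_ids},
        coverage={s: float(coverage[s]) for s in table.sample_ids},
    )
    return table.subset_samples(keep), report


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Standardize counts by per-sample read totals; columns sum to 1."""
    depths = table.depths()
    if (depths == 0).any():
        raise ValueError("zero-depth sample; filter samples first")
    return table.counts / depths


def _parse_lineage(lineage: str) -> list[str]:
    """Return names per rank; '' where unclassified. Accepts short lineages."""
    names = [""] * len(RANKS)
    if not lineage or not isinstance(lineage, str):
        return names
    for i, token in enumerate(t.strip() for t in lineage.split(";")):
        if i >= len(RANKS):
            break
        name = token
        if token.lower().startswith(_RANK_PREFIXES[i]):
            name = token[3:]
        if name.strip().lower() in ("", "unclassified", "none", "na"):
            name = ""
        names[i] = name.strip()
    return names


def aggregate_taxonomy(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts over OTUs sharing a lineage at ``rank``.

    OTUs unclassified at that rank pool into ``"unclassified <parent>"``
    where the parent is the deepest classified ancestor ("unclassified
    root" when none). Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    group_of: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    for otu in table.otu_ids:
        names = _parse_lineage(table.taxonomy.get(otu, ""))
        if names[level]:
            key = names[level]
            lineage = ";".join(
                _RANK_PREFIXES[i] + names[i] for i in range(level + 1)
            )
        else:
            parent = next(
                (names[i] for i in range(level - 1, -1, -1) if names[i]), "root"
            )
            key = f"unclassified {parent}"
            lineage = key
        group_of[otu] = key
        lineage_of.setdefault(key, lineage)
    grouped = table.counts.groupby(
        pd.Index([group_of[o] for o in table.otu_ids]), sort=True
    ).sum()
    grouped.index.name = "taxon"
    return OtuTable(grouped, {k: lineage_of[k] for k in grouped.index})
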