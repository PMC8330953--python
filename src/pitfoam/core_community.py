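"""Core-community membership and differential abundance per texture.

The "core" community of a texture group is the set of taxa present (count
> 0) in at least a prevalence fraction of that group's samples — by
default all of them, which suppresses farm-specific membership. Cores are
compared with a Venn partition of shared and unique members, and rank-
aggregated taxa are screened for differential relative abundance across
textures with the JZS ANOVA Bayes factor (decisive-evidence thresholds of
100 at genus and 20 at species rank by convention), with bootstrap
percentile confidence intervals on per-texture mean abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .amplicon_qc import OtuTable
from .trend_bayes import bf_anova

__all__ = [
    "CoreSet",
    "DiffAbundanceRecord",
    "core_taxa",
    "venn_partition",
    "bootstrap_ci",
    "differential_abundance",
    "diff_abundance_to_frame",
]

#: default Bayes-factor thresholds per taxonomic rank
BF_THRESHOLDS = {"genus": 100.0, "species": 20.0}


@dataclass
class CoreSet:
    group: str
    members: set
    prevalence_threshold: float


@dataclass
class DiffAbundanceRecord:
    taxon: str
    rank: str
    group_means: dict[str, float]
    group_cis: dict[str, tuple]
    bf10: float
    significant: bool
    most_abundant_in: str = ""


def core_taxa(
    table: OtuTable,
    metadata: pd.DataFrame,
    group: str,
    prevalence: float = 1.0,
    group_col: str = "texture",
) -> CoreSet:
    """Taxa present in at least ``prevalence`` of the group's samples.

    ``prevalence = 1.0`` (default) requires presence in every sample of
    the group; ``prevalence = 0`` degenerates to any taxon observed at
    least once.
    """
    if not (0 <= prevalence <= 1):
        raise ValueError("prevalence must be in [0, 1]")
    members = metadata.index[metadata[group_col] == group]
    members = [m for m in members if m in table.counts.columns]
    if len(members) == 0:
        raise ValueError(f"no samples in group {group!r}")
    presence = (table.counts.loc[:, members] > 0).mean(axis=1)
    if prevalence == 0:
        keep = presence > 0
    else:
        keep = presence >= prevalence
    return CoreSet(
        group=group,
        members=set(table.counts.index[keep]),
        prevalence_threshold=prevalence,
    )


def venn_partition(cores) -> dict[str, int]:
    """Counts for every exclusive region of the core-set Venn diagram.

    Region keys join group names with '&' (e.g. ``"crust&foam"`` is the
    set of taxa in both those cores and no other); counts sum to the size
    of the union.
    """
    if len(cores) < 2:
        raise ValueError("need at least 2 core sets")
    names = [c.group for c in cores]
    if len(set(names)) != len(names):
        raise ValueError("core sets must have distinct group names")
    sets = {c.group: c.members for c in cores}
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[g] for g in combo))
            for other in names:
                if other not in combo:
                    inside -= sets[other]
            out["&".join(combo)] = len(inside)
    return out


def bootstrap_ci(
    values, n_boot: int = 999, level: float = 0.95, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for the mean: (lower, mean, upper)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 5:
        raise ValueError("need at least 5 values")
    rng = np.random.default_rng(seed)
    means = rng.choice(arr, size=(n_boot, len(arr)), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lower), float(arr.mean()), float(upper)


def differential_abundance(
    relabund_at_rank: pd.DataFrame,
    metadata: pd.DataFrame,
    rank: str,
    bf_threshold: float | None = None,
    group_col: str = "texture",
    n_boot: int = 999,
    seed: int = 0,
    prior_scale: float = 0.5,
) -> list[DiffAbundanceRecord]:
    """Screen rank-aggregated relative abundances for texture differences.

    ``relabund_at_rank`` is taxa x samples (columns matched to metadata
    rows). Each taxon is tested with the JZS ANOVA Bayes factor across
    textures and flagged significant at ``bf_threshold`` (rank-specific
    default: 100 at genus, 20 at species, else 100). Taxa whose abundance
    is degenerate (all zero or constant) are reported with bf10 = NaN.
    """
    if bf_threshold is None:
        bf_threshold = BF_THRESHOLDS.get(rank, 100.0)
    common = [s for s in relabund_at_rank.columns if s in metadata.index]
    data = relabund_at_rank.loc[:, common]
    groups = metadata.loc[common, group_col].to_numpy()
    labels = list(pd.unique(groups))
    records = []
    for ti, taxon in enumerate(data.index):
        vals = data.loc[taxon].to_numpy(dtype=float)
        means = {g: float(vals[groups == g].mean()) for g in labels}
        cis = {}
        for gi, g in enumerate(labels):
            gv = vals[groups == g]
            if len(gv) >= 5:
                cis[g] = bootstrap_ci(gv, n_boot=n_boot, seed=seed + 97 * ti + gi)
            else:
                cis[g] = (float("nan"), float(gv.mean()), float("nan"))
        try:
            bf = bf_anova(vals, groups, prior_scale=prior_scale)
        except ValueError:
            bf = float("nan")
        records.append(
            DiffAbundanceRecord(
                taxon=str(taxon),
                rank=rank,
                group_means=means,
                group_cis=cis,
                bf10=bf,
                significant=bool(np.isfinite(bf) and bf >= bf_threshold),
                most_abundant_in=max(means, key=means.get),
            )
        )
    records.sort(key=lambda r: -max(r.group_means.values()))
    return records


def diff_abundance_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"taxon": r.taxon, "rank": r.rank}
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
            row[f"ci_lower_{g}"] = r.group_cis[g][0]
            row[f"ci_upper_{g}"] = r.group_cis[g][2]
        row.update(
            {
                "BF10": r.bf10,
                "significant": r.significant,
                "most_abundant_in": r.most_abundant_in,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
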