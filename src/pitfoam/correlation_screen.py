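"""Monotonic vs non-monotonic dependence screening per texture group.

Pairwise relationships between variables (diet inputs, manure chemistry,
or taxa relative abundances) are classified within each texture group:

* **monotonic** when the Benjamini-Hochberg-adjusted Spearman p-value is
  below alpha; strength is |rho|;
* **non-monotonic** when the Spearman test is not significant but the
  adjusted Hoeffding dependence test is; strength is Hoeffding's D;
* **none** otherwise.

Hoeffding's D is a rank statistic sensitive to any form of dependence,
including U-shaped relationships invisible to Spearman. It is computed
here from mid-ranks with half-corrections for ties, and its p-value by a
seeded permutation test. BH adjustment is applied within each (texture
group, test family) separately, matching per-group reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationRecord",
    "spearman",
    "hoeffding_d",
    "bh_adjust",
    "classify",
    "screen",
    "records_to_frame",
]


@dataclass
class CorrelationRecord:
    var_a: str
    var_b: str
    group: str
    n: int
    spearman_rho: float
    spearman_p: float
    spearman_p_adj: float
    hoeffding_D: float
    hoeffding_p: float
    hoeffding_p_adj: float
    classification: str  # monotonic | non-monotonic | none | skipped
    strength: float
    sign: int
    reason: str = ""


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value.

    Pairs with missing values are dropped; a constant input is an error
    (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _midranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _hoeffding_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D (x30 scaling, max 1) from mid-ranks.

    ``Q_i`` counts points with both coordinates below point i, with
    half-credit for ties in either coordinate (quarter for ties in both).
    """
    n = len(x)
    if n < 5:
        raise ValueError("Hoeffding's D needs n >= 5")
    R = _midranks(x)
    S = _midranks(y)
    ux = (x[None, :] < x[:, None]) + 0.5 * (x[None, :] == x[:, None])
    uy = (y[None, :] < y[:, None]) + 0.5 * (y[None, :] == y[:, None])
    Q = (ux * uy).sum(axis=1) - 0.25  # remove the i==j term (0.5*0.5)
    A = ((R - 1) * (R - 2) * (S - 1) * (S - 2)).sum()
    B = ((R - 2) * (S - 2) * Q).sum()
    C = (Q * (Q - 1)).sum()
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return float(30.0 * (A - 2 * (n - 2) * B + (n - 2) * (n - 3) * C) / denom)


def hoeffding_d(x, y, n_perm: int = 199, seed: int = 0) -> tuple[float, float]:
    """Hoeffding's dependence statistic D with a permutation p-value.

    The p-value is ``(1 + #{permuted D >= observed}) / (1 + n_perm)``
    under random re-pairings of y against x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    d_obs = _hoeffding_stat(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _hoeffding_stat(x, y[rng.permutation(len(y))]) >= d_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return d_obs, float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(spearman_p_adj: float, hoeffding_p_adj: float, alpha: float = 0.05) -> str:
    """Monotonic if Spearman significant; non-monotonic if only Hoeffding."""
    if spearman_p_adj < alpha:
        return "monotonic"
    if hoeffding_p_adj < alpha:
        return "non-monotonic"
    return "none"


def screen(
    data: pd.DataFrame,
    groups,
    pairs,
    alpha: float = 0.05,
    top_k: int = 5,
    n_perm: int = 199,
    seed: int = 0,
    min_n: int = 8,
) -> list[CorrelationRecord]:
    """Test the requested variable pairs within every texture group.

    ``data`` is samples x variables; ``groups`` is the texture factor
    aligned to its rows. BH adjustment runs within each (group, test)
    family. Groups with fewer than ``min_n`` complete pairs for a
    comparison skip it with a logged reason. Records classified other than
    "none" are ranked within their classification type by strength; use
    :func:`strongest` to extract the top-k per group.
    """
    groups = pd.Series(np.asarray(groups), index=data.index)
    records: list[CorrelationRecord] = []
    for gi, group in enumerate(pd.unique(groups)):
        sub = data.loc[groups == group]
        tested: list[CorrelationRecord] = []
        for pi, (var_a, var_b) in enumerate(pairs):
            if var_a not in data.columns or var_b not in data.columns:
                raise KeyError(f"pair ({var_a}, {var_b}) not in data columns")
            x = sub[var_a].to_numpy(dtype=float)
            y = sub[var_b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_n:
                records.append(
                    CorrelationRecord(
                        var_a, var_b, str(group), n,
                        np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                        "skipped", np.nan, 0,
                        reason=f"only {n} complete pairs (min {min_n})",
                    )
                )
                continue
            rho, sp = spearman(x[ok], y[ok])
            D, hp = hoeffding_d(
                x[ok], y[ok], n_perm=n_perm, seed=seed + 1000 * gi + pi
            )
            tested.append(
                CorrelationRecord(
                    var_a, var_b, str(group), n,
                    rho, sp, np.nan, D, hp, np.nan,
                    "none", np.nan, int(np.sign(rho)),
                )
            )
        if tested:
            s_adj = bh_adjust([r.spearman_p for r in tested])
            h_adj = bh_adjust([r.hoeffding_p for r in tested])
            for r, sa, ha in zip(tested, s_adj, h_adj):
                r.spearman_p_adj = float(sa)
                r.hoeffding_p_adj = float(ha)
                r.classification = classify(sa, ha, alpha)
                if r.classification == "monotonic":
                    r.strength = abs(r.spearman_rho)
                elif r.classification == "non-monotonic":
                    r.strength = r.hoeffding_D
                else:
                    r.strength = 0.0
        records.extend(tested)
    return records


def strongest(records, k: int = 5) -> dict[str, list[CorrelationRecord]]:
    """Top-k associations per group, interleaving classification types by
    within-type strength rank (|rho| and D are not on one scale, so
    cross-type order follows within-type rank, monotonic first on ties)."""
    out: dict[str, list[CorrelationRecord]] = {}
    for group in {r.group for r in records}:
        sig = [
            r
            for r in records
            if r.group == group and r.classification in ("monotonic", "non-monotonic")
        ]
        ranked = []
        for kind in ("monotonic", "non-monotonic"):
            members = sorted(
                (r for r in sig if r.classification == kind), key=lambda r: -r.strength
            )
            ranked.extend(
                (rank, 0 if kind == "monotonic" else 1, r)
                for rank, r in enumerate(members)
            )
        ranked.sort(key=lambda t: (t[0], t[1]))
        out[group] = [r for _, _, r in ranked[: max(k, 0)]]
    return out


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "var_a": r.var_a,
                "var_b": r.var_b,
                "n": r.n,
                "spearman_rho": r.spearman_rho,
                "spearman_p": r.spearman_p,
                "spearman_p_adj": r.spearman_p_adj,
                "hoeffding_D": r.hoeffding_D,
                "hoeffding_p": r.hoeffding_p,
                "hoeffding_p_adj": r.hoeffding_p_adj,
                "classification": r.classification,
                "strength": r.strength,
                "sign": r.sign,
                "reason": r.reason,
            }
            for r in records
        ]
    )
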