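"""Community ecology statistics: Bray-Curtis, PERMANOVA, NMDS, env surfaces.

All four are implemented from first principles on top of numpy/scipy/
scikit-learn primitives:

* Bray-Curtis dissimilarity ``d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)``;
* one-factor PERMANOVA on squared dissimilarities with optional restricted
  (within-stratum) permutations, for blocked designs such as repeated
  samples of the same farm;
* non-metric multidimensional scaling (NMDS) minimizing Kruskal stress-1
  via SMACOF majorization interleaved with isotonic regression (primary
  tie approach);
* a quadratic polynomial surface fit of an environmental variable onto
  ordination coordinates (a deterministic stand-in for contour fitting
  of, e.g., methane production rate over an ordination).

The distance container is scikit-bio's :class:`~skbio.DistanceMatrix`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from skbio import DistanceMatrix

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "OrdinationResult",
    "EnvSurfaceFit",
    "bray_curtis",
    "permanova",
    "nmds",
    "fit_env_surface",
]


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    grouping: str = "group"
    strata: str | None = None

    def as_row(self) -> dict:
        return {
            "factor": self.grouping,
            "strata": self.strata or "",
            "pseudo_F": self.pseudo_F,
            "R2": self.R2,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n_samples x k
    stress: float
    n_restarts: int
    converged: bool
    sample_ids: list = field(default_factory=list)
    stress_history: np.ndarray | None = None


@dataclass
class EnvSurfaceFit:
    variable: str
    fitted: np.ndarray
    R2: float


def bray_curtis(abundances, sample_ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    ``abundances`` is a features x samples matrix (DataFrame or array) of
    non-negative values — raw counts or relative abundances; the statistic
    is invariant to a common positive rescaling of each sample.
    """
    if isinstance(abundances, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(abundances.columns)
        X = abundances.to_numpy(dtype=float)
    else:
        X = np.asarray(abundances, dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = X.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("all-zero sample; Bray-Curtis undefined")
    n = X.shape[1]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    D = np.zeros((n, n))
    # d = 1 - 2*sum(min)/(s_i + s_j), computed one column against the rest
    for i in range(n - 1):
        mins = np.minimum(X[:, i + 1 :], X[:, [i]]).sum(axis=0)
        D[i, i + 1 :] = 1.0 - 2.0 * mins / (totals[i + 1 :] + totals[i])
    D = np.clip(D + D.T, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids=[str(s) for s in sample_ids])


def _align_factor(values, ids) -> np.ndarray:
    if isinstance(values, pd.Series):
        return values.reindex(list(ids)).to_numpy()
    arr = np.asarray(values)
    if len(arr) != len(ids):
        raise ValueError("factor not aligned with distance matrix")
    return arr


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Anderson's one-factor partition of squared dissimilarities."""
    n = len(codes)
    ss_total = D2.sum() / (2.0 * n)
    onehot = np.zeros((n, n_groups))
    onehot[np.arange(n), codes] = 1.0
    sizes = onehot.sum(axis=0)
    block_sums = np.einsum("ia,ij,ja->a", onehot, D2, onehot)
    ss_within = float((block_sums / (2.0 * sizes)).sum())
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        f = np.inf
    else:
        f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _distinct_label_permutations(labels: np.ndarray, cap: int = 200_000):
    perms = set()
    for p in itertools.permutations(labels.tolist()):
        perms.add(p)
        if len(perms) > cap:
            raise ValueError("too many distinct permutations for exact test")
    return [np.asarray(p) for p in sorted(perms)]


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    strata=None,
    seed: int | None = 0,
    method: str = "sampled",
    grouping_name: str = "group",
    strata_name: str | None = None,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    ``pseudo_F`` follows the standard partition of squared dissimilarities
    (``SS_total = sum_{i<j} d_ij^2 / N`` etc.); the p-value counts permuted
    F statistics at least as large as the observed one, with the +1
    correction so that p >= 1/(n_perm + 1). When ``strata`` is given,
    group labels are permuted only within each stratum — the restricted
    permutation scheme for blocked designs (e.g. farms as blocks). With
    ``method="exact"`` all distinct label rearrangements are enumerated
    instead of sampled (only feasible for small n).
    """
    groups = _align_factor(grouping, dm.ids)
    labels, codes = np.unique(groups, return_counts=False), None
    codes = np.searchsorted(labels, groups)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least 2 groups")
    D2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs, r2 = _pseudo_f(D2, codes, a)

    if method == "exact":
        if strata is not None:
            raise ValueError("exact enumeration does not support strata")
        perms = _distinct_label_permutations(codes)
        count = sum(_pseudo_f(D2, p, a)[0] >= f_obs for p in perms)
        p_value = count / len(perms)
        n_used = len(perms) - 1
    elif method == "sampled":
        rng = np.random.default_rng(seed)
        if strata is not None:
            strata_arr = _align_factor(strata, dm.ids)
            stratum_idx = [
                np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)
            ]
        else:
            stratum_idx = [np.arange(len(codes))]
        count = 0
        perm_codes = codes.copy()
        for _ in range(n_perm):
            for idx in stratum_idx:
                perm_codes[idx] = codes[rng.permutation(idx)]
            if _pseudo_f(D2, perm_codes, a)[0] >= f_obs:
                count += 1
        p_value = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")

    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=float(p_value),
        n_permutations=n_used,
        grouping=grouping_name,
        strata=strata_name if strata is not None else None,
    )


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _condensed(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], 1)
    return D[iu]


def _config_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return _condensed(np.sqrt((diff**2).sum(-1)))


def _smacof_run(
    delta: np.ndarray, n: int, k: int, X0: np.ndarray, max_iter: int, tol: float
):
    """Nonmetric SMACOF: isotonic disparities + Guttman transform.

    The recorded stress sequence is non-increasing by construction: an
    iteration that would raise stress is discarded and iteration stops.
    """
    order = np.lexsort((np.arange(len(delta)), delta))  # primary tie approach
    iu = np.triu_indices(n, 1)
    X = X0.copy()
    d = _config_distances(X)
    history = []
    stress = np.inf
    converged = False
    for _ in range(max_iter):
        dhat_sorted = isotonic_regression(d[order]).x
        dhat = np.empty_like(d)
        dhat[order] = dhat_sorted
        denom = (d**2).sum()
        if denom == 0:
            break
        dhat = dhat * np.sqrt(denom / max((dhat**2).sum(), 1e-300))
        new_stress = np.sqrt(((d - dhat) ** 2).sum() / denom)
        if new_stress > stress:  # keep the previous, better configuration
            break
        improved = stress - new_stress
        stress = new_stress
        history.append(stress)
        if improved < tol:
            converged = True
            break
        # Guttman transform with unit weights
        ratio = np.zeros_like(d)
        nonzero = d > 1e-12
        ratio[nonzero] = dhat[nonzero] / d[nonzero]
        B = np.zeros((n, n))
        B[iu] = -ratio
        B = B + B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = (B @ X) / n
        X = X_new
        d = _config_distances(X)
    return X, float(stress), converged, np.asarray(history)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Restart 0 starts from classical (metric) scaling; the remaining
    restarts are random. The best configuration over restarts is returned.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError("k must be < n_samples")
    delta = _condensed(D)
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(n_restarts, 1)):
        X0 = _classical_mds(D, k) if restart == 0 else rng.standard_normal((n, k))
        X, stress, converged, history = _smacof_run(delta, n, k, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, converged, history)
    X, stress, converged, history = best
    return OrdinationResult(
        coordinates=X,
        stress=stress,
        n_restarts=max(n_restarts, 1),
        converged=converged,
        sample_ids=list(dm.ids),
        stress_history=history,
    )


def _quadratic_design(coords: np.ndarray) -> np.ndarray:
    n, k = coords.shape
    cols = [np.ones(n)]
    for i in range(k):
        cols.append(coords[:, i])
    for i in range(k):
        for j in range(i, k):
            cols.append(coords[:, i] * coords[:, j])
    return np.column_stack(cols)


def fit_env_surface(ordination, env, variable: str = "env") -> EnvSurfaceFit:
    """Least-squares fit of an environmental variable on a full quadratic
    polynomial in the ordination coordinates; rows with missing env values
    are dropped before fitting (fitted values are NaN there)."""
    coords = (
        ordination.coordinates
        if isinstance(ordination, OrdinationResult)
        else np.asarray(ordination, dtype=float)
    )
    env = np.asarray(env, dtype=float)
    if len(env) != coords.shape[0]:
        raise ValueError("env not aligned with ordination samples")
    ok = np.isfinite(env)
    X = _quadratic_design(coords[ok])
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer samples than polynomial terms")
    y = env[ok]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        r2 = 0.0  # constant env: no variance to explain
    else:
        r2 = float(np.clip(1.0 - ((y - yhat) ** 2).sum() / ss_tot, 0.0, 1.0))
    fitted = np.full(len(env), np.nan)
    fitted[ok] = yhat
    return EnvSurfaceFit(variable=variable, fitted=fitted, R2=r2)
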