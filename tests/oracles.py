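"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a statistic by the most literal route available —
explicit double loops, full enumeration, or direct numerical integration
of the defining integrals — deliberately sharing no code with the package
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.integrate import simpson


def bray_curtis_brute(X: np.ndarray) -> np.ndarray:
    """Pairwise sum|x-y| / sum(x+y) over columns, by explicit loops."""
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(abs(X[k, i] - X[k, j]) for k in range(X.shape[0]))
            den = sum(X[k, i] + X[k, j] for k in range(X.shape[0]))
            D[i, j] = num / den
    return D


def hoeffding_d_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D via direct double loops over all point pairs."""
    n = len(x)

    def midrank(v, i):
        less = sum(1 for j in range(n) if v[j] < v[i])
        ties = sum(1 for j in range(n) if v[j] == v[i])  # includes i
        return less + (ties + 1) / 2.0

    R = [midrank(x, i) for i in range(n)]
    S = [midrank(y, i) for i in range(n)]

    def u(a, b):
        return 1.0 if b < a else (0.5 if b == a else 0.0)

    Q = []
    for i in range(n):
        q = 0.0
        for j in range(n):
            if j == i:
                continue
            q += u(x[i], x[j]) * u(y[i], y[j])
        Q.append(q)
    A = sum((R[i] - 1) * (R[i] - 2) * (S[i] - 1) * (S[i] - 2) for i in range(n))
    B = sum((R[i] - 2) * (S[i] - 2) * Q[i] for i in range(n))
    C = sum(Q[i] * (Q[i] - 1) for i in range(n))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * (A - 2 * (n - 2) * B + (n - 2) * (n - 3) * C) / denom


def bh_step_up_brute(p: list[float]) -> list[float]:
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def permanova_f_brute(D: np.ndarray, labels) -> float:
    """Pseudo-F from the definitional sums over unordered pairs."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_total = sum(D[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_g = sum(
            D[i][j] ** 2 for k, i in enumerate(idx) for j in idx[k + 1 :]
        )
        ss_within += ss_g / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_exact_p_brute(D: np.ndarray, labels) -> float:
    """Permutation p by full enumeration of distinct label arrangements."""
    f_obs = permanova_f_brute(D, labels)
    perms = sorted(set(itertools.permutations(labels)))
    count = sum(permanova_f_brute(D, p) >= f_obs for p in perms)
    return count / len(perms)


def jzs_two_sample_bf_brute(
    x: np.ndarray, y: np.ndarray, cauchy_scale: float
) -> float:
    """JZS two-sample Bayes factor by brute-force double integration.

    Marginalizes the likelihood of the observed t statistic over the
    standardized effect delta ~ Cauchy(0, scale) written as its
    normal/inverse-gamma mixture: inner integral over delta | g on a
    standardized grid, outer integral over log g. Uses only the
    noncentral-t density — an entirely different route from the linear-
    algebra marginalization inside the package.
    """
    n1, n2 = len(x), len(y)
    nu = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / nu
    t_obs = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))

    z = np.linspace(-12, 12, 601)
    phi = stats.norm.pdf(z)
    log_g = np.linspace(-30, 30, 601)
    g = np.exp(log_g)
    # inverse-gamma(1/2, scale^2/2) density times the log-grid Jacobian g
    r2 = cauchy_scale**2
    from scipy.special import gamma as gamma_fn

    w = np.sqrt(r2 / 2.0) / gamma_fn(0.5) * g ** (-1.5) * np.exp(-r2 / (2 * g)) * g
    inner = np.empty(len(g))
    for k, gk in enumerate(g):
        delta = np.sqrt(gk) * z
        inner[k] = simpson(stats.nct.pdf(t_obs, nu, delta * np.sqrt(neff)) * phi, x=z)
    m1 = simpson(inner * w, x=log_g)
    m0 = stats.t.pdf(t_obs, nu)
    return m1 / m0
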