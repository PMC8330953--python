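"""Bootstrap time-decay analysis of community stability per texture group.

For each manure texture the Bray-Curtis dissimilarity between pairs of
samples from the *same farm* is regressed on the time lag between them
with an exponential model ``y = a * exp(b * x)``; the per-month slope b
measures how fast the community drifts, so a smaller b means a more
stable community. Pairing is restricted to within-farm pairs because
between-farm dissimilarity is dominated by the farm effect and would
swamp the temporal signal.

The sampling distribution of b is estimated by bootstrapping the group's
samples (with replacement, each sample keeping its farm identity),
rebuilding the lag pairs and refitting — 999 replicates by default.
Slope distributions of two groups are compared descriptively with the
overlap coefficient (OVL), the integral of the pointwise minimum of two
Gaussian kernel density estimates; OVL near 0 means clearly separated
stability regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde

from .ecology_stats import bray_curtis

__all__ = [
    "StabilityFit",
    "OverlapResult",
    "ExponentialFitError",
    "lag_pairs",
    "fit_exponential",
    "bootstrap_slopes",
    "overlap_coefficient",
    "pairwise_overlap",
]

_LOG_EPS = 1e-6  # guards log of zero dissimilarities in the initializer


class ExponentialFitError(RuntimeError):
    """Nonlinear fit failed; carries the log-linear fallback parameters."""

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


@dataclass
class StabilityFit:
    group: str
    pairs_used: int
    a_hat: float
    b_hat: float
    bootstrap_slopes: np.ndarray
    n_boot: int
    seed: int
    n_failed_replicates: int = 0


@dataclass
class OverlapResult:
    group_a: str
    group_b: str
    ovl: float


def lag_pairs(
    relabund: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    group_col: str = "texture",
    farm_col: str = "farm",
    month_col: str = "month",
) -> list[tuple[int, float]]:
    """(time lag in months, Bray-Curtis) for within-farm same-group pairs.

    ``relabund`` is OTUs x samples; only unordered pairs of samples from
    the same farm, both carrying the requested texture, are emitted, and
    zero-lag pairs are excluded.
    """
    members = metadata.index[metadata[group_col] == group]
    if len(members) == 0:
        raise ValueError(f"no samples in group {group!r}")
    if len(members) < 2:
        return []
    sub = relabund.loc[:, members]
    dm = bray_curtis(sub)
    D = np.asarray(dm.data)
    farms = metadata.loc[members, farm_col].to_numpy()
    months = metadata.loc[members, month_col].to_numpy()
    i, j = np.triu_indices(len(members), 1)
    sel = (farms[i] == farms[j]) & (months[i] != months[j])
    lags = np.abs(months[i] - months[j])[sel]
    vals = D[i, j][sel]
    return list(zip(lags.tolist(), vals.tolist()))


def fit_exponential(pairs) -> tuple[float, float]:
    """Nonlinear least squares of y on ``a * exp(b * x)``.

    Initialized from the linear fit of log(y + eps) on x; requires at
    least 3 distinct x values and non-negative y. On non-convergence an
    :class:`ExponentialFitError` carrying the log-linear fallback is
    raised.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (x, y)")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values")
    if (y < 0).any():
        raise ValueError("y must be non-negative")
    b0, loga0 = np.polyfit(x, np.log(y + _LOG_EPS), 1)
    p0 = (float(np.exp(loga0)), float(b0))
    try:
        popt, _ = curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y, p0=p0, maxfev=5000
        )
    except RuntimeError as err:
        raise ExponentialFitError(str(err), fallback=p0) from err
    return float(popt[0]), float(popt[1])


def bootstrap_slopes(
    relabund: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    n_boot: int = 999,
    seed: int = 0,
    group_col: str = "texture",
    farm_col: str = "farm",
    month_col: str = "month",
    max_failed_frac: float = 0.2,
) -> StabilityFit:
    """Bootstrap distribution of the exponential slope for one group.

    Samples (not farms) are the resampling unit; each resampled sample
    keeps its farm identity, lag pairs are rebuilt among the resampled
    multiset, and the exponential is refit. Replicates that cannot be fit
    (too few distinct lags or non-convergence) are redrawn; more than
    ``max_failed_frac * n_boot`` failures is an error.
    """
    members = metadata.index[metadata[group_col] == group]
    if len(members) < 2:
        raise ValueError(f"group {group!r} too small for a fit")
    sub = relabund.loc[:, members]
    D = np.asarray(bray_curtis(sub).data)
    farms = metadata.loc[members, farm_col].to_numpy()
    months = metadata.loc[members, month_col].to_numpy(dtype=float)
    n = len(members)
    iu, ju = np.triu_indices(n, 1)

    full_sel = (farms[iu] == farms[ju]) & (months[iu] != months[ju])
    full_pairs = np.column_stack(
        [np.abs(months[iu] - months[ju])[full_sel], D[iu, ju][full_sel]]
    )
    a_hat, b_hat = fit_exponential(full_pairs)

    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    failed = 0
    max_failed = int(np.ceil(max_failed_frac * n_boot))
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, n)
        fi, fj = farms[idx[iu]], farms[idx[ju]]
        mi, mj = months[idx[iu]], months[idx[ju]]
        sel = (fi == fj) & (mi != mj)
        if sel.sum() < 3 or len(np.unique(np.abs(mi - mj)[sel])) < 3:
            failed += 1
            if failed > max_failed:
                raise RuntimeError(
                    f"more than {max_failed} failed bootstrap replicates"
                )
            continue
        pairs = np.column_stack(
            [np.abs(mi - mj)[sel], D[idx[iu], idx[ju]][sel]]
        )
        try:
            _, b = fit_exponential(pairs)
        except (ExponentialFitError, ValueError):
            failed += 1
            if failed > max_failed:
                raise RuntimeError(
                    f"more than {max_failed} failed bootstrap replicates"
                )
            continue
        slopes[filled] = b
        filled += 1

    return StabilityFit(
        group=group,
        pairs_used=len(full_pairs),
        a_hat=a_hat,
        b_hat=b_hat,
        bootstrap_slopes=slopes,
        n_boot=n_boot,
        seed=seed,
        n_failed_replicates=failed,
    )


def overlap_coefficient(slopes_a, slopes_b, grid_points: int = 512) -> float:
    """Overlap coefficient of two samples' kernel density estimates.

    OVL = integral of min(f_a, f_b) over a shared grid; the densities are
    Gaussian KDEs with Silverman's bandwidth, integrated by the trapezoid
    rule. 1 means indistinguishable distributions, 0 disjoint ones.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("need at least 10 values per sample")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (zero-variance) slope vector")
    kde_a = gaussian_kde(a, bw_method="silverman")
    kde_b = gaussian_kde(b, bw_method="silverman")
    bw = max(kde_a.factor * a.std(ddof=1), kde_b.factor * b.std(ddof=1))
    lo = min(a.min(), b.min()) - 4 * bw
    hi = max(a.max(), b.max()) + 4 * bw
    grid = np.linspace(lo, hi, max(grid_points, 512))
    fa = kde_a(grid)
    fb = kde_b(grid)
    return float(np.clip(np.trapezoid(np.minimum(fa, fb), grid), 0.0, 1.0))


def pairwise_overlap(fits) -> list[OverlapResult]:
    """OVL for every unordered pair of stability fits."""
    out = []
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            out.append(
                OverlapResult(
                    group_a=fits[i].group,
                    group_b=fits[j].group,
                    ovl=overlap_coefficient(
                        fits[i].bootstrap_slopes, fits[j].bootstrap_slopes
                    ),
                )
            )
    return out
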