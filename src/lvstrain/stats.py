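"""Nonparametric cohort statistics for small serial-imaging cohorts.

Medians with distribution-free order-statistic confidence intervals, a
Kruskal-Wallis gate across timepoints, pairwise Mann-Whitney follow-up
(exact by full enumeration at the study's sample sizes), Bonferroni
thresholding, and Pearson/Spearman correlation of strain metrics with
scalar covariates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "GroupSample",
    "TestResult",
    "median_ci",
    "kruskal_wallis",
    "mann_whitney",
    "bonferroni_threshold",
    "correlate",
]

#: largest pooled sample for which the exact Mann-Whitney enumeration is
#: chosen automatically (C(12, 6) = 924 labelings)
EXACT_POOLED_LIMIT = 12


@dataclass(frozen=True)
class GroupSample:
    """A labelled group of per-subject scalars."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise ParameterError("group needs at least one value")
        if not np.all(np.isfinite(v)):
            raise ParameterError(f"group {self.label!r} has non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]


def median_ci(
    sample: GroupSample | np.ndarray, level: float = 0.95
) -> tuple[float, float, float, float]:
    """Median with a distribution-free order-statistic confidence interval.

    Picks the smallest symmetric order-statistic pair ``[x_(j), x_(n+1-j)]``
    whose exact binomial coverage ``1 - 2 P(Bin(n, 1/2) <= j - 1)`` reaches
    ``level``.  When even the full range falls short (always for n <= 5 at
    0.95) the full range is returned with its achieved coverage and a
    warning.  Returns ``(median, lo, hi, achieved_coverage)``.
    """
    values = sample.values if isinstance(sample, GroupSample) else np.asarray(sample, float)
    x = np.sort(values)
    n = len(x)
    med = float(np.median(x))

    def coverage(j: int) -> float:
        # coverage of [x_(j), x_(n+1-j)], 1-indexed j
        return float(1.0 - 2.0 * sps.binom.cdf(j - 1, n, 0.5))

    best_j = None
    for j in range(n // 2, 0, -1):  # narrowest symmetric pair first
        if coverage(j) >= level:
            best_j = j
            break
    if best_j is None:
        achieved = coverage(1) if n >= 1 else float("nan")
        warnings.warn(
            f"n={n}: no symmetric order-statistic interval reaches "
            f"{level:.0%} coverage; returning the sample range "
            f"(achieved {max(achieved, 0.0):.1%})",
            stacklevel=2,
        )
        return med, float(x[0]), float(x[-1]), max(achieved, 0.0)
    return med, float(x[best_j - 1]), float(x[n - best_j]), coverage(best_j)


def kruskal_wallis(groups: list[GroupSample]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared (k-1 df) p-value."""
    if len(groups) < 2:
        raise ParameterError("Kruskal-Wallis needs at least 2 groups")
    arrays = [g.values for g in groups]
    n_total = sum(len(a) for a in arrays)
    if n_total < 3:
        raise ParameterError("Kruskal-Wallis needs total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(len(a) for a in arrays))
    stat, p = sps.kruskal(*arrays)
    return TestResult(float(stat), float(p), "kruskal_wallis", tuple(len(a) for a in arrays))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x: #(x > y) pairs + half-credit for ties."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by full enumeration of C(nx+ny, nx) labelings.

    Uses pooled midranks so tied data are handled exactly; two-sided
    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))).
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    offset = nx * (nx + 1) / 2.0
    u_obs = _u_statistic(x, y)
    total = math.comb(nx + ny, nx)
    n_le = n_ge = 0
    eps = 1e-9
    for combo in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(combo)].sum() - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def _normal_mw_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie-corrected variance, no continuity
    correction (so the two-group Kruskal-Wallis identity chi2_1 = z^2 holds)."""
    nx, ny = len(x), len(y)
    u = _u_statistic(x, y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - nx * ny / 2.0) / math.sqrt(sigma2)
    return u, float(2.0 * sps.norm.sf(abs(z)))


def mann_whitney(x: GroupSample, y: GroupSample, mode: str = "auto") -> TestResult:
    """Mann-Whitney U test, exact by enumeration for small pooled samples.

    ``mode='auto'`` enumerates all labelings when nx + ny <= 12, otherwise
    falls back to the tie-corrected normal approximation; ``'exact'`` and
    ``'normal'`` force a path.
    """
    xv, yv = x.values, y.values
    pooled_n = len(xv) + len(yv)
    if mode == "auto":
        mode = "exact" if pooled_n <= EXACT_POOLED_LIMIT else "normal"
    if mode == "exact":
        u, p = _exact_mw_p(xv, yv)
        method = "mann_whitney_exact"
    elif mode == "normal":
        u, p = _normal_mw_p(xv, yv)
        method = "mann_whitney_normal"
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return TestResult(u, p, method, (len(xv), len(yv)))


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ParameterError(f"number of hypotheses m must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    return alpha / m


#: pooled n at or below which the Spearman p-value is an exact permutation
SPEARMAN_EXACT_LIMIT = 8


def correlate(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> tuple[float, float, float]:
    """Correlation of paired scalars: ``(coefficient, R^2, p_two_sided)``.

    Pearson p comes from the t distribution with n-2 df.  Spearman p is an
    exact permutation over all n! orderings for n <= 8, scipy's asymptotic
    approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("correlate needs >= 3 finite pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("correlate needs finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        return float(r), float(r) ** 2, float(p)
    if method == "spearman":
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho = float(sps.pearsonr(rx, ry)[0])
        n = len(x)
        if n <= SPEARMAN_EXACT_LIMIT:
            perms = np.array(list(itertools.permutations(ry)))
            rxc = rx - rx.mean()
            pc = perms - ry.mean()
            denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
            rhos = pc @ rxc / denom
            p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        else:
            p = float(sps.spearmanr(x, y).pvalue)
        return rho, rho**2, p
    raise ParameterError(f"unknown correlation method {method!r}")
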