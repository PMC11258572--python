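"""Nonparametric inference toolkit with exact small-sample paths.

Implements the four procedures the longitudinal analysis relies on:
Mann-Whitney U, matched-pair Wilcoxon signed-rank, Spearman rank
correlation with permutation p-values, and Cohen's d.  Conventions:

* mid-ranks everywhere ties occur;
* exact null distributions by complete enumeration for small samples
  (Mann-Whitney and Wilcoxon via count-constrained subset-sum dynamics on
  doubled mid-ranks, which remains valid under ties; Spearman by full
  permutation enumeration up to n = 8, seeded Monte-Carlo permutation
  beyond, with the identity permutation counted in both numerator and
  denominator);
* two-sided p-values for the rank tests double the smaller one-sided tail,
  capped at 1; the permutation p for Spearman is inherently two-sided on
  |rho|;
* large samples fall back to normal approximations with tie and continuity
  corrections;
* Wilcoxon drops zero differences (classic treatment);
* no multiple-comparison correction anywhere.

Every result records which path produced it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "StatResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "spearman_exact",
    "cohens_d",
    "EXACT_LIMIT_RANKSUM",
    "EXACT_LIMIT_SPEARMAN",
]

EXACT_LIMIT_RANKSUM = 20   # max n1+n2 (MW) or n (Wilcoxon) for enumeration
EXACT_LIMIT_SPEARMAN = 8   # max n for full n! enumeration


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    method: str
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    effect_size: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _two_sided(p_le: float, p_ge: float) -> float:
    return min(1.0, 2.0 * min(p_le, p_ge))


def _subset_sum_counts(weights: np.ndarray, size: int) -> np.ndarray:
    """counts[s] = number of ``size``-subsets of ``weights`` with sum s.

    Weights are non-negative integers (doubled mid-ranks).  Exact in float64
    for the n <= 20 regime (counts <= C(20,10) << 2^53).
    """
    total = int(weights.sum())
    dp = np.zeros((size + 1, total + 1))
    dp[0, 0] = 1.0
    for w in weights:
        w = int(w)
        upd = dp[:-1, : total + 1 - w].copy()
        dp[1:, w:] += upd
    return dp[size]


def _signed_rank_counts(weights: np.ndarray) -> np.ndarray:
    """counts[s] = number of sign patterns whose positive-rank sum is s."""
    total = int(weights.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for w in weights:
        w = int(w)
        dp[w:] += dp[: total + 1 - w].copy()
    return dp


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

def mann_whitney_u(
    x,
    y,
    alternative: str = "two-sided",
    exact_with_ties: bool = False,
    with_effect_size: bool = False,
) -> StatResult:
    """Mann-Whitney U test of two independent samples.

    The statistic is U for the first sample (number of (x, y) pairs with
    x > y, counting ties as half).  Exact enumeration is used when
    n1 + n2 <= 20 and the pooled data are tie-free (or ``exact_with_ties``
    is set, in which case the enumeration conditions on the observed
    mid-ranks); otherwise a normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    N = n1 + n2

    if N <= EXACT_LIMIT_RANKSUM and (not has_ties or exact_with_ties):
        doubled = np.rint(2 * ranks).astype(int)
        counts = _subset_sum_counts(doubled, n1)
        total = counts.sum()
        s_obs = int(round(2 * r1))
        sums = np.arange(counts.size)
        p_le = counts[sums <= s_obs].sum() / total
        p_ge = counts[sums >= s_obs].sum() / total
        method = "exact_enumeration" + ("_ties" if has_ties else "")
        if alternative == "two-sided":
            p = _two_sided(p_le, p_ge)
        elif alternative == "greater":
            p = p_ge
        else:
            p = p_le
    else:
        mu = n1 * n2 / 2.0
        tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
        var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "two-sided":
                z = (abs(u1 - mu) - 0.5) / sd
                p = min(1.0, 2.0 * norm.sf(z))
            elif alternative == "greater":
                p = float(norm.sf((u1 - mu - 0.5) / sd))
            else:
                p = float(norm.cdf((u1 - mu + 0.5) / sd))
        method = "normal_approx_tie_corrected"

    eff = cohens_d(x, y) if with_effect_size and n1 >= 2 and n2 >= 2 else None
    return StatResult(
        statistic=float(u1), p_value=float(p), method=method,
        n=N, n1=n1, n2=n2, effect_size=eff,
    )


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

def wilcoxon_signed_rank(
    paired_diffs, alternative: str = "two-sided", exact_with_ties: bool = False
) -> StatResult:
    """Matched-pair Wilcoxon signed-rank test on within-subject differences.

    Zero differences are dropped; |differences| are mid-ranked; the
    statistic is W+, the sum of ranks of positive differences.  Exact 2^n
    sign-pattern enumeration (via subset-sum dynamics) when n <= 20 and the
    |differences| are tie-free (or ``exact_with_ties``); otherwise normal
    approximation with tie and continuity corrections.
    """
    d = np.asarray(paired_diffs, dtype=float)
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: no information")

    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n <= EXACT_LIMIT_RANKSUM and (not has_ties or exact_with_ties):
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_counts(doubled)
        total = counts.sum()  # 2^n
        s_obs = int(round(2 * w_plus))
        sums = np.arange(counts.size)
        p_le = counts[sums <= s_obs].sum() / total
        p_ge = counts[sums >= s_obs].sum() / total
        method = "exact_enumeration" + ("_ties" if has_ties else "")
        if alternative == "two-sided":
            p = _two_sided(p_le, p_ge)
        elif alternative == "greater":
            p = p_ge
        else:
            p = p_le
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "two-sided":
                z = (abs(w_plus - mu) - 0.5) / sd
                p = min(1.0, 2.0 * norm.sf(z))
            elif alternative == "greater":
                p = float(norm.sf((w_plus - mu - 0.5) / sd))
            else:
                p = float(norm.cdf((w_plus - mu + 0.5) / sd))
        method = "normal_approx_tie_corrected"

    return StatResult(statistic=float(w_plus), p_value=float(p), method=method, n=n)


# --------------------------------------------------------------------------
# Spearman with permutation p-values
# --------------------------------------------------------------------------

def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_exact(
    x, y, n_resamples: int = 100_000, seed=None, force_monte_carlo: bool = False
) -> StatResult:
    """Spearman rho with an exact (or Monte-Carlo) permutation p-value.

    rho is the Pearson correlation of mid-ranks.  For n <= 8 the p-value is
    the exact proportion of the n! permutations of the y-ranks whose |rho|
    reaches |rho_obs| (within 1e-12).  For larger n a seeded Monte-Carlo
    permutation test is used, counting the observed permutation in both
    numerator and denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant sample")

    rx = rankdata(x)
    ry = rankdata(y)
    rho = _rank_corr(rx, ry)
    thresh = abs(rho) - 1e-12

    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc @ rxc) * (ryc @ ryc))

    if n <= EXACT_LIMIT_SPEARMAN and not force_monte_carlo:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (ryc[perms] @ rxc) / denom
        p = float((np.abs(rho_perm) >= thresh).mean())
        method = "exact_permutation"
        used_seed = None
    else:
        if n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        rng = np.random.default_rng(seed)
        perm_ranks = rng.permuted(
            np.broadcast_to(ryc, (n_resamples, n)).copy(), axis=1
        )
        rho_perm = perm_ranks @ rxc / denom
        hits = int((np.abs(rho_perm) >= thresh).sum())
        p = (1.0 + hits) / (1.0 + n_resamples)
        method = "monte_carlo_permutation"
        used_seed = int(seed) if isinstance(seed, (int, np.integer)) else None

    return StatResult(
        statistic=rho, p_value=float(p), method=method, n=n, seed=used_seed
    )


# --------------------------------------------------------------------------
# effect size
# --------------------------------------------------------------------------

def cohens_d(x, y) -> float:
    """Cohen's d with pooled SD; first argument patients, second controls,
    so lower patient values give negative d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d needs at least 2 observations per group")
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if pooled <= 0:
        raise ValueError("zero pooled variance: effect size undefined")
    return float((x.mean() - y.mean()) / math.sqrt(pooled))
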