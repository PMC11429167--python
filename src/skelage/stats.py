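"""Rank-based comparisons, correlation, the normality gate and descriptives.

Small skeletochronological samples with heavily tied integer ages call
for rank methods with explicit tie handling: midranks everywhere, a
tie-corrected normal approximation (with continuity correction) for the
Mann–Whitney U, Spearman's rho as the product-moment correlation of
midranks, and a Shapiro–Wilk gate deciding whether the nonparametric
branch is taken. The numeric kernels are scipy.stats; this module fixes
the conventions (min-U reporting, the Σd²-style S statistic, Fisher-z
confidence intervals) and the result containers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "MannWhitneyMethod",
    "MannWhitneyResult",
    "SpearmanResult",
    "NormalityDecision",
    "DescriptiveStats",
    "midranks",
    "mann_whitney_u",
    "spearman",
    "shapiro_wilk_gate",
    "describe",
]


class MannWhitneyMethod(enum.Enum):
    NORMAL_APPROX_TIE_CORRECTED = "normal_approx_tie_corrected"
    EXACT = "exact"


@dataclass(frozen=True)
class MannWhitneyResult:
    """U in the classical min(u1, u2) reporting convention.

    u1 is the first sample's U (number of (x, y) pairs with x > y, ties
    half); u1 + u2 = n1·n2.
    """

    u: float
    u1: float
    u2: float
    p: float
    method: MannWhitneyMethod


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    s_stat: float  # (1 - rho) * n (n^2 - 1) / 6, the Σd²-style statistic
    p: float
    n: int
    ci95: tuple[float, float] | None = None


@dataclass(frozen=True)
class NormalityDecision:
    w: float
    p: float
    normal: bool
    alpha: float


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    sd: float  # sample sd, denominator n - 1; 0 by convention when n = 1
    min: float
    max: float


def midranks(values) -> np.ndarray:
    """Ranks 1..n with tied values sharing the mean of their occupied ranks."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("midranks of an empty sequence")
    return sps.rankdata(arr, method="average")


def mann_whitney_u(x, y, method: str | MannWhitneyMethod = "asymptotic") -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    The default p-value uses the tie-corrected normal approximation with
    continuity correction; ``method="exact"`` enumerates the null
    distribution (tie-free samples only), and ``method="auto"`` picks
    exact when n1·n2 <= 400 and the pooled sample is tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if isinstance(method, MannWhitneyMethod):
        method = "exact" if method is MannWhitneyMethod.EXACT else "asymptotic"
    if method == "auto":
        scipy_method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    elif method in ("exact", "asymptotic"):
        scipy_method = method
        if scipy_method == "exact" and has_ties:
            raise ValueError("exact method unavailable with ties")
    else:
        raise ValueError(f"unknown method {method!r}")

    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=scipy_method, use_continuity=True
    )
    u1 = float(res.statistic)
    u2 = n1 * n2 - u1
    return MannWhitneyResult(
        u=min(u1, u2),
        u1=u1,
        u2=u2,
        p=float(res.pvalue),
        method=MannWhitneyMethod.EXACT
        if scipy_method == "exact"
        else MannWhitneyMethod.NORMAL_APPROX_TIE_CORRECTED,
    )


def spearman(x, y, ci: bool = True) -> SpearmanResult:
    """Spearman rank correlation with tie-aware midranks.

    rho is the product-moment correlation of midranks; the companion
    statistic S = (1 − rho)·n(n² − 1)/6 (equal to Σd² in the tie-free
    case); p from the t approximation with n − 2 df; optional 95% CI via
    the Fisher z transform with SE 1/sqrt(n − 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined: a rank vector has zero variance")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    s_stat = (1.0 - rho) * n * (n**2 - 1) / 6.0
    ci95 = None
    if ci and n > 3 and abs(rho) < 1:
        z = math.atanh(rho)
        half = sps.norm.ppf(0.975) / math.sqrt(n - 3)
        ci95 = (math.tanh(z - half), math.tanh(z + half))
    return SpearmanResult(rho=rho, s_stat=float(s_stat), p=float(res.pvalue), n=n, ci95=ci95)


def shapiro_wilk_gate(values, alpha: float = 0.05) -> NormalityDecision:
    """Shapiro–Wilk test as a branch gate: ``normal = (p >= alpha)``.

    A ``normal=False`` decision routes the pipeline to the
    nonparametric comparisons. Requires 3 <= n <= 5000 and non-constant
    data.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro–Wilk requires n >= 3")
    if arr.size > 5000:
        raise ValueError("Shapiro–Wilk limited to n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro–Wilk undefined for constant data (zero variance)")
    w, p = sps.shapiro(arr)
    return NormalityDecision(w=float(w), p=float(p), normal=bool(p >= alpha), alpha=alpha)


def describe(values) -> DescriptiveStats:
    """n, mean, sample sd (n − 1 denominator), min, max."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("describe of an empty sample")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return DescriptiveStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )
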