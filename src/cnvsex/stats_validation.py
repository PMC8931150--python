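"""Validation statistics for a CNV-based sexing assay.

Covers the battery used to validate dosage assays: descriptive summaries
per sex, a histogram-based bimodality amplitude, paired t-tests for
biological-replicate agreement, Shapiro–Wilk normality of replicate
differences, the phi association coefficient against morphologically
determined sex, and a chi-square goodness of fit against a 1:1 sex ratio.

The p-value machinery (Student t, Shapiro–Wilk via the Royston AS R94
approximation, chi-square tails) delegates to scipy.stats; the assay-
specific statistics are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CohortSummary",
    "StatResult",
    "descriptive_summary",
    "bimodality_amplitude",
    "paired_t",
    "shapiro_wilk",
    "phi_coefficient",
    "chi_square_1to1",
]


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of a cohort's CNV values."""

    n: int
    mean: float
    sd: float  # sample SD, n−1 denominator
    ci95_halfwidth: float  # t-based
    min: float
    max: float
    cv: float  # sd / mean
    ba: Optional[float] = None  # bimodality amplitude, when relevant


@dataclass(frozen=True)
class StatResult:
    statistic_name: str  # t_paired | W_shapiro | phi | chi2_gof | BA
    value: float
    df: Optional[int] = None
    p_value: Optional[float] = None


def descriptive_summary(values: Sequence[float]) -> CohortSummary:
    """Mean, sample SD, t-based 95% CI half-width, range, and CV."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values for a summary, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    ci = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return CohortSummary(
        n=n, mean=mean, sd=sd, ci95_halfwidth=ci,
        min=float(x.min()), max=float(x.max()),
        cv=sd / mean if mean != 0 else float("nan"),
    )


def _local_maxima(counts: np.ndarray) -> list[int]:
    """Indices of local maxima, collapsing plateaus to their first bin.

    A run of equal non-zero counts is a maximum when both flanking bins
    (or array edges) are strictly lower.
    """
    peaks: list[int] = []
    n = counts.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left_lower = i == 0 or counts[i - 1] < counts[i]
        right_lower = j == n - 1 or counts[j + 1] < counts[i]
        if counts[i] > 0 and left_lower and right_lower:
            peaks.append(i)
        i = j + 1
    return peaks


def bimodality_amplitude(
    values: Sequence[float],
    bin_width: float = 0.1,
    value_range: tuple[float, float] = (0.0, 3.0),
) -> StatResult:
    """Histogram-based bimodality amplitude.

    BA = (A_s − A_v) / A_s, with A_s the height of the smaller of the two
    tallest local-maximum bins and A_v the minimum bin height between
    them.  BA = 1 means fully separated modes (empty valley); a sample
    with fewer than two local maxima scores 0 by convention.  Binning is
    fixed-width (default 0.1 over [0, 3]), which suits copy numbers
    clustering at 1 and 2.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 values for bimodality, got {x.size}")
    lo, hi = value_range
    nbins = int(round((hi - lo) / bin_width))
    counts, _ = np.histogram(x, bins=nbins, range=(lo, hi))
    peaks = _local_maxima(counts)
    if len(peaks) < 2:
        return StatResult("BA", 0.0)
    top_two = sorted(sorted(peaks, key=lambda i: -counts[i])[:2])
    left, right = top_two
    a_s = float(min(counts[left], counts[right]))
    a_v = float(counts[left + 1:right].min()) if right > left + 1 else a_s
    return StatResult("BA", (a_s - a_v) / a_s)


def paired_t(
    values_rep1: Sequence[float], values_rep2: Sequence[float]
) -> StatResult:
    """Paired-sample t-test on matched biological replicates.

    t = mean(d) / (sd(d)/√n) with d = rep1 − rep2, df = n − 1, two-sided
    p.  Identical vectors have zero-variance differences and no defined
    statistic, so that case raises rather than returning ±inf.
    """
    a = np.asarray(values_rep1, dtype=float)
    b = np.asarray(values_rep2, dtype=float)
    if a.size != b.size:
        raise ValueError("replicate vectors must be the same length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of replicate differences: test degenerate")
    res = stats.ttest_rel(a, b)
    return StatResult("t_paired", float(res.statistic), df=a.size - 1,
                      p_value=float(res.pvalue))


def shapiro_wilk(values: Sequence[float]) -> StatResult:
    """Shapiro–Wilk normality test (Royston AS R94 approximation)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro–Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro–Wilk approximation valid only up to n = 5000")
    w, p = stats.shapiro(x)
    return StatResult("W_shapiro", float(w), p_value=float(p))


def phi_coefficient(a: int, b: int, c: int, d: int) -> StatResult:
    """Phi association for a 2×2 confusion table.

    Cells are (true F ∧ called F, true F ∧ called M, true M ∧ called F,
    true M ∧ called M).  Φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)); the
    p-value comes from χ² = nΦ² on 1 df.  Any zero margin leaves the
    coefficient undefined.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: association undefined")
    n = a + b + c + d
    phi = (a * d - b * c) / math.sqrt(math.prod(margins))
    chi2 = n * phi * phi
    return StatResult("phi", phi, df=1, p_value=float(stats.chi2.sf(chi2, 1)))


def chi_square_1to1(n_f: int, n_m: int) -> StatResult:
    """Pearson goodness of fit of observed sex counts against 1:1.

    χ² = Σ(obs − exp)²/exp with exp = (n_f + n_m)/2, df = 1, no
    continuity correction.
    """
    if n_f < 0 or n_m < 0:
        raise ValueError("counts must be non-negative")
    total = n_f + n_m
    if total < 1:
        raise ValueError("need at least one observation")
    expected = total / 2.0
    chi2 = (n_f - expected) ** 2 / expected + (n_m - expected) ** 2 / expected
    return StatResult("chi2_gof", float(chi2), df=1,
                      p_value=float(stats.chi2.sf(chi2, 1)))
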