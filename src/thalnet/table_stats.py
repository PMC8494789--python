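"""Demographic/clinical comparison statistics (Table-1 style).

Two-sample t tests from group summaries (Student or Welch, with an F-ratio
variance-equality screen in auto mode), uncorrected Pearson chi-square and
Fisher's exact test for 2x2 categorical tables. All p values two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats


@dataclass
class GroupSummary:
    """Mean/SD/n per group for a continuous variable."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SD must be non-negative")


VarianceRule = Literal["auto", "student", "welch"]


def variances_equal(summary: GroupSummary, alpha: float = 0.05) -> bool:
    """Two-sided F-ratio screen for equality of variances."""
    hi, lo = sorted([(summary.sd1, summary.n1), (summary.sd2, summary.n2)],
                    key=lambda p: p[0], reverse=True)
    if lo[0] == 0:
        return hi[0] == 0
    F = (hi[0] / lo[0]) ** 2
    p = 2.0 * stats.f.sf(F, hi[1] - 1, lo[1] - 1)
    return min(p, 1.0) >= alpha


def two_sample_t(summary: GroupSummary, variance_rule: VarianceRule = "auto"
                 ) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics.

    Returns (t, df, two-sided p). ``student`` pools variances; ``welch``
    uses the Satterthwaite df; ``auto`` picks Welch when the F screen
    rejects equality at 0.05.
    """
    if variance_rule == "auto":
        variance_rule = "student" if variances_equal(summary) else "welch"
    t, p = stats.ttest_ind_from_stats(
        summary.mean1, summary.sd1, summary.n1,
        summary.mean2, summary.sd2, summary.n2,
        equal_var=(variance_rule == "student"))
    if variance_rule == "student":
        df = float(summary.n1 + summary.n2 - 2)
    else:
        v1 = summary.sd1**2 / summary.n1
        v2 = summary.sd2**2 / summary.n2
        df = (v1 + v2) ** 2 / (v1**2 / (summary.n1 - 1) + v2**2 / (summary.n2 - 1))
    return float(t), float(df), float(p)


def _check_2x2(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    return counts


def chi_square_2x2(counts) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square on a 2x2 table: (chi2, df=1, p)."""
    counts = _check_2x2(counts)
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def fisher_exact_2x2(counts) -> float:
    """Two-sided Fisher's exact p (hypergeometric tail summation)."""
    counts = _check_2x2(counts)
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return float(p)
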