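"""Statistical support operations shared by the analysis modules.

Thin, contract-stable wrappers around scipy/statsmodels: Benjamini–Hochberg
FDR adjustment and the handful of test families the analyses call
(one- and two-sample t, Wilcoxon signed-rank, Wilcoxon rank-sum, and an
Anderson–Darling normality screen).  Degenerate inputs (all-tied pairs,
zero variance) are handled explicitly instead of propagating NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "fdr_adjust", "test", "TEST_KINDS"]

TEST_KINDS = (
    "one_sample_t",
    "two_sample_t",
    "signed_rank_paired",
    "rank_sum",
    "normality_screen",
)

_SIDES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``n`` records the sample size(s) involved; ``adjusted_p`` is filled in
    only when the result has passed through :func:`fdr_adjust` as part of a
    battery.
    """

    kind: str
    statistic: float
    p_value: float
    sidedness: str
    n: tuple[int, ...]
    adjusted_p: float | None = None


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Returns adjusted values in the same order as the input.  Adjusted values
    are monotone in the sorted order and never below the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _degenerate(x) -> bool:
    x = np.asarray(x, dtype=float)
    return x.size > 0 and np.ptp(x) == 0.0


def test(kind, x, y=None, sidedness="two-sided", popmean=0.0) -> TestResult:
    """Run one of the supported hypothesis tests.

    Parameters
    ----------
    kind:
        One of ``one_sample_t``, ``two_sample_t``, ``signed_rank_paired``,
        ``rank_sum``, ``normality_screen``.
    x, y:
        Sample(s).  ``y`` is required for the two-sample and paired kinds and
        ignored otherwise.
    sidedness:
        ``two-sided`` (default), ``less`` or ``greater``.  Ignored for the
        normality screen.
    popmean:
        Null value for the one-sample t-test.

    Rank-based tests use exact small-sample null distributions when scipy's
    ``auto`` policy allows (no ties, n ≤ 25) and a tie-corrected normal
    approximation otherwise.
    """
    if kind not in TEST_KINDS:
        raise ValueError(f"unknown test kind {kind!r}")
    if sidedness not in _SIDES:
        raise ValueError(f"sidedness must be one of {_SIDES}")
    x = np.asarray(x, dtype=float)

    if kind == "normality_screen":
        if x.size < 3:
            raise ValueError("normality screen needs at least 3 observations")
        stat, p = normal_ad(x)
        return TestResult(kind, float(stat), float(p), "two-sided", (x.size,))

    if kind == "one_sample_t":
        if x.size < 2:
            raise ValueError("one-sample t needs at least 2 observations")
        if _degenerate(x):
            # Zero variance: the t statistic is undefined; report the
            # limiting p-value and flag it.
            warnings.warn("zero-variance sample in one_sample_t", stacklevel=2)
            if x[0] == popmean:
                return TestResult(kind, 0.0, 1.0, sidedness, (x.size,))
            sign = np.sign(x[0] - popmean)
            if sidedness == "two-sided":
                p = 0.0
            elif sidedness == "greater":
                p = 0.0 if sign > 0 else 1.0
            else:
                p = 0.0 if sign < 0 else 1.0
            return TestResult(kind, float(sign * np.inf), p, sidedness, (x.size,))
        res = sps.ttest_1samp(x, popmean, alternative=sidedness)
        return TestResult(kind, float(res.statistic), float(res.pvalue), sidedness, (x.size,))

    y = np.asarray(y, dtype=float)

    if kind == "two_sample_t":
        if x.size < 2 or y.size < 2:
            raise ValueError("two-sample t needs at least 2 observations per group")
        res = sps.ttest_ind(x, y, alternative=sidedness)
        return TestResult(kind, float(res.statistic), float(res.pvalue), sidedness, (x.size, y.size))

    if kind == "signed_rank_paired":
        if x.size != y.size or x.size < 1:
            raise ValueError("paired test needs equal-length, non-empty samples")
        d = x - y
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return TestResult(kind, 0.0, 1.0, sidedness, (x.size,))
        res = sps.wilcoxon(x, y, alternative=sidedness, mode="auto")
        return TestResult(kind, float(res.statistic), float(res.pvalue), sidedness, (x.size,))

    # rank_sum
    if x.size < 2 or y.size < 2:
        raise ValueError("rank-sum needs at least 2 observations per group")
    pooled = np.concatenate([x, y])
    if _degenerate(pooled):
        warnings.warn("all observations tied in rank_sum; p = 1", stacklevel=2)
        return TestResult(kind, float(x.size * y.size / 2), 1.0, sidedness, (x.size, y.size))
    res = sps.mannwhitneyu(x, y, alternative=sidedness, method="auto")
    return TestResult(kind, float(res.statistic), float(res.pvalue), sidedness, (x.size, y.size))
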