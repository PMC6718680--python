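"""Cohort-level statistical comparisons.

Outlier removal (iterative two-sided Grubbs), log-normality checks of
first-occurrence times (Kolmogorov-Smirnov against a moment-fitted
log-normal; Shapiro-Wilk on logs), the paired one-tailed t-test on
log-times (with an optional ratio-shifted null), and the one-tailed
Mann-Whitney comparison of slope distributions.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "grubbs_filter",
    "lognormal_tests",
    "paired_log_test",
    "mann_whitney_one_tailed",
]


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size ``n``."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier removal at level ``alpha``.

    Returns ``(kept, outliers)``. Removal repeats until no point exceeds
    the critical value or fewer than three points remain; zero-variance
    samples are left untouched.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires at least three values")
    kept = x.copy()
    outliers = []
    while kept.size >= 3:
        sd = kept.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(kept - kept.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical(kept.size, alpha):
            outliers.append(kept[i])
            kept = np.delete(kept, i)
        else:
            break
    return kept, np.asarray(outliers)


def lognormal_tests(times) -> tuple[float, float, float, float]:
    """Log-normality checks of positive first-occurrence times.

    Kolmogorov-Smirnov against a log-normal with parameters estimated
    from the log-moments, plus Shapiro-Wilk on the log-transformed
    values. Returns ``(ks_stat, ks_p, sw_stat, sw_p)``.
    """
    x = np.asarray(times, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three values")
    if np.any(x <= 0):
        raise ValueError("times must be positive")
    logs = np.log(x)
    mu, sigma = logs.mean(), logs.std(ddof=1)
    if sigma == 0:
        raise ValueError("degenerate sample with zero spread")
    ks = stats.kstest(x, "lognorm", args=(sigma, 0.0, np.exp(mu)))
    sw = stats.shapiro(logs)
    return float(ks.statistic), float(ks.pvalue), float(sw.statistic), float(sw.pvalue)


def paired_log_test(
    t_as, t_ies, ratio: float | None = None
) -> tuple[float, float]:
    """Paired one-tailed t-test on ``ln(t_ies) - ln(t_as)``.

    The alternative is that the difference exceeds zero, or ``ln(ratio)``
    when a ratio-shifted null is requested (the published analysis
    considers a fivefold ratio). Returns ``(t_stat, one_tailed_p)``;
    an exactly null sample yields ``(0, 0.5)``.
    """
    a = np.asarray(t_as, dtype=float)
    b = np.asarray(t_ies, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples of equal length required")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("times must be positive")
    shift = np.log(ratio) if ratio is not None else 0.0
    d = np.log(b) - np.log(a) - shift
    if np.allclose(d, 0):
        return 0.0, 0.5
    res = stats.ttest_1samp(d, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_one_tailed(group1, group2) -> tuple[float, float]:
    """One-tailed Mann-Whitney U test (H1: group1 shifted below group2).

    Exact null distribution when the smaller sample has at most eight
    values and there are no ties; the tie-corrected normal approximation
    otherwise.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(g1.size, g2.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="less", method=method)
    return float(res.statistic), float(res.pvalue)
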