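"""Two-sample t-tests: Student, Welch, and paired.

The null hypothesis throughout is H0: mu_a - mu_b = 0, tested two-sided.
Which unpaired variant applies is a property of the scenario, not of the
samples: Welch's modification is used if and only if the population
variances of the two data-generating processes differ (no pre-testing of
sample variances).

Snapped data can be constant, so degenerate samples get explicit
conventions: zero standard error with equal means -> p = 1 (t = 0); zero
standard error with unequal means -> p = 0 (t = +/- inf).

Batch helpers (`unpaired_pvalues`, `paired_pvalues`) evaluate one test per
row of 2-D arrays; the scalar API wraps them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "unpaired_t",
    "paired_t",
    "unpaired_pvalues",
    "paired_pvalues",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    reject: bool
    alpha: float


def _two_sided_p(t: np.ndarray, df) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def _finalize(t, df, se, mean_diff):
    """Apply degenerate-sample conventions and compute two-sided p-values."""
    zero_se = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, 0.0, t)
        df_safe = np.where(np.isfinite(df) & (df > 0), df, 1.0)
        p = _two_sided_p(t, df_safe)
    p = np.where(zero_se & (mean_diff == 0.0), 1.0, p)
    p = np.where(zero_se & (mean_diff != 0.0), 0.0, p)
    t = np.where(zero_se & (mean_diff != 0.0), np.copysign(np.inf, mean_diff), t)
    return t, p


def unpaired_pvalues(x: np.ndarray, y: np.ndarray, welch: bool):
    """Row-wise unpaired t-tests; returns (t, df, p) arrays."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    diff = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, float(n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t, p = _finalize(t, df, se, diff)
    return t, df, p


def paired_pvalues(x: np.ndarray, y: np.ndarray):
    """Row-wise paired t-tests (one-sample t on differences)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal shapes")
    n = x.shape[1]
    if n < 2:
        raise ValueError("paired test needs at least 2 pairs")
    d = x - y
    md = d.mean(axis=1)
    se = np.sqrt(d.var(axis=1, ddof=1) / n)
    df = np.full_like(se, float(n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / se
    t, p = _finalize(t, df, se, md)
    return t, df, p


def unpaired_t(x, y, welch: bool = False, alpha: float = 0.05) -> TestResult:
    """Unpaired two-sample t-test of H0: mu_a - mu_b = 0, two-sided.

    Student's pooled-variance form (df = n1 + n2 - 2) when ``welch`` is
    False; Welch's form with Satterthwaite df otherwise. ``welch`` should
    be set from the scenario's population variances.
    """
    t, df, p = unpaired_pvalues(np.asarray(x, float)[None, :],
                                np.asarray(y, float)[None, :], welch)
    return TestResult(float(t[0]), float(df[0]), float(p[0]),
                      bool(p[0] < alpha), alpha)


def paired_t(x, y, alpha: float = 0.05) -> TestResult:
    """Paired t-test: one-sample t on the differences, df = n - 1."""
    t, df, p = paired_pvalues(np.asarray(x, float)[None, :],
                              np.asarray(y, float)[None, :])
    return TestResult(float(t[0]), float(df[0]), float(p[0]),
                      bool(p[0] < alpha), alpha)
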