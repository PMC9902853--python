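"""Longitudinal statistics for two-timepoint PET parameters.

Percentage change, annualisation, paired tests, Pearson correlation,
Bland–Altman agreement between two measures of change, and paired-t
sample-size curves based on the noncentral t distribution.

All tests are two-sided.  No multiple-testing correction is applied by
default (regional P values are reported raw); a Bonferroni helper is
available for users who need familywise control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlandAltmanResult",
    "SampleSizeResult",
    "percentage_change",
    "annualized_change",
    "paired_t",
    "pearson",
    "bland_altman",
    "power_paired",
    "sample_size_paired",
    "sample_size_curve",
    "bonferroni",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired measurement methods.

    ``bias`` is the mean of (method A - method B); limits of agreement
    are ``bias ± 1.96 * sd_diff``.
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


@dataclass(frozen=True)
class SampleSizeResult:
    """Required pairs for a two-sided paired t test."""

    expected_pct_change: float
    sd_pct_change: float
    alpha: float
    power: float
    n_required: int


def percentage_change(baseline, followup):
    """``(follow-up / baseline - 1) * 100`` (elementwise)."""
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline values must be positive")
    out = (followup / baseline - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def annualized_change(pct_change, interval_years):
    """Percentage change per year: ``pct_change / interval``."""
    interval = np.asarray(interval_years, dtype=float)
    if np.any(interval <= 0):
        raise ValueError("interval must be positive")
    out = np.asarray(pct_change, dtype=float) / interval
    return float(out) if out.ndim == 0 else out


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t test; returns (t statistic, p value).

    Identical vectors are the degenerate null case and return (0, 1);
    constant non-zero differences have no finite t statistic and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of size >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise ValueError("differences have zero variance")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must not be constant")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(method_a, method_b) -> BlandAltmanResult:
    """Bland–Altman bias and 95% limits of agreement.

    Differences are ``method_a - method_b`` (by convention the fully
    quantitative measure minus the semiquantitative one).
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length 1-D vectors of size >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_pairs=a.size,
    )


def power_paired(n: int, dz: float, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t test at ``n`` pairs.

    ``dz`` is the standardised effect (mean difference over SD of
    differences); power is evaluated under the noncentral t distribution
    with ``df = n - 1`` and noncentrality ``dz * sqrt(n)``.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1
    ncp = dz * np.sqrt(n)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_paired(
    mean_change: float,
    sd_change: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_max: int = 100_000,
) -> SampleSizeResult:
    """Smallest ``n >= 2`` giving the requested power for a paired t test.

    The effect is framed as an expected percentage change and the SD of
    percentage change (matching how longitudinal PET effects are quoted);
    ``dz = mean_change / sd_change`` internally.
    """
    if sd_change <= 0:
        raise ValueError("sd_change must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    dz = abs(mean_change) / sd_change
    if dz == 0:
        raise ValueError("zero effect size has no finite sample size")
    n = 2
    while n <= n_max:
        if power_paired(n, dz, alpha) >= power:
            return SampleSizeResult(
                expected_pct_change=mean_change,
                sd_pct_change=sd_change,
                alpha=alpha,
                power=power,
                n_required=n,
            )
        n += 1
    raise ValueError("no n below n_max reaches the requested power")


def sample_size_curve(
    effect_grid,
    sd_change: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> list[SampleSizeResult]:
    """Required n across a grid of expected percentage changes
    (e.g. 0.5% to 10%) at a fixed SD of change."""
    return [
        sample_size_paired(float(e), sd_change, alpha, power) for e in effect_grid
    ]


def bonferroni(p_values, n_tests: int | None = None):
    """Bonferroni-adjusted p values (optional familywise control)."""
    p = np.asarray(p_values, dtype=float)
    m = n_tests if n_tests is not None else p.size
    return np.minimum(p * m, 1.0)
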