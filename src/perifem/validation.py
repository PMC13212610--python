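"""Agreement and diagnostic-accuracy statistics for paired validation studies.

Bland-Altman agreement (bias, limits of agreement, one-sample t-test of the
differences), threshold classification of hemodynamic significance (resting
gradient > 10 mmHg, FFR < 0.8; both strict), confusion-matrix proportions,
and exact Clopper-Pearson binomial confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RESTING_GRADIENT_THRESHOLD_MMHG",
    "FFR_THRESHOLD",
    "AgreementSummary",
    "DiagnosticSummary",
    "bland_altman",
    "classify_resting",
    "classify_ffr",
    "confusion",
    "clopper_pearson",
    "round_half_away",
]

RESTING_GRADIENT_THRESHOLD_MMHG = 10.0
FFR_THRESHOLD = 0.8


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with halves away from zero (the convention of clinical tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman summary of simulated minus measured differences."""

    n: int
    bias: float  # mean difference
    sd: float  # sample SD of the differences (n-1 denominator)
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    t_statistic: float  # one-sample t of the differences against 0; nan if sd == 0
    p_value: float  # two-sided; nan if sd == 0
    pearson_r: float  # correlation of (measured, simulated)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("agreement analysis needs at least 2 pairs")
        if abs((self.loa_high - self.loa_low) - 2 * 1.96 * self.sd) > 1e-9:
            raise ValueError("limits of agreement inconsistent with bias +/- 1.96 sd")

    @property
    def significant_bias(self) -> bool:
        """True when the mean difference differs from zero at alpha = 0.05."""
        return bool(np.isfinite(self.p_value) and self.p_value < 0.05)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Confusion counts with proportions and exact 95% intervals.

    ``degenerate_*`` flags mark proportions whose denominator leaves the
    interval resting on a single observation or none (e.g. specificity from
    one true negative).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]
    ci_accuracy: tuple[float, float]
    degenerate_sensitivity: bool = False
    degenerate_specificity: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def bland_altman(measured: np.ndarray, simulated: np.ndarray) -> AgreementSummary:
    """Bland-Altman analysis of simulated versus measured values.

    Differences are simulated minus measured, so a negative bias means the
    simulation underestimates.  Limits of agreement are bias +/- 1.96 SD
    with the sample (n-1) standard deviation; the t-test is a two-sided
    one-sample test of the differences against zero.
    """
    m = np.asarray(measured, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if m.shape != s.shape or m.ndim != 1:
        raise ValueError("measured and simulated must be 1-D arrays of equal length")
    if m.size < 2:
        raise ValueError("agreement analysis needs at least 2 pairs")
    d = s - m
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        t_stat, p = float("nan"), float("nan")
    else:
        res = stats.ttest_1samp(d, 0.0)
        t_stat, p = float(res.statistic), float(res.pvalue)
    if np.std(m) == 0.0 or np.std(s) == 0.0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(m, s).statistic)
    return AgreementSummary(
        n=m.size,
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        t_statistic=t_stat,
        p_value=p,
        pearson_r=r,
    )


def classify_resting(gradient: float, threshold: float = RESTING_GRADIENT_THRESHOLD_MMHG) -> bool:
    """Hemodynamically significant iff the resting gradient strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return gradient > threshold


def classify_ffr(value: float, threshold: float = FFR_THRESHOLD) -> bool:
    """Hemodynamically significant iff FFR is strictly below the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("FFR threshold must lie in (0, 1)")
    return value < threshold


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles.

    Lower bound is the level-appropriate quantile of Beta(k, n-k+1) (0 when
    k = 0); upper bound the quantile of Beta(k+1, n-k) (1 when k = n).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lo, hi


def confusion(predicted: np.ndarray, truth: np.ndarray, level: float = 0.95) -> DiagnosticSummary:
    """Diagnostic summary of a binary classification against reference truth."""
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("predicted and truth must be 1-D boolean arrays of equal length >= 1")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    n = p.size
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / n
    ci_sens = clopper_pearson(tp, n_pos, level) if n_pos else (float("nan"), float("nan"))
    ci_spec = clopper_pearson(tn, n_neg, level) if n_neg else (float("nan"), float("nan"))
    ci_acc = clopper_pearson(tp + tn, n, level)
    return DiagnosticSummary(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        ci_sensitivity=ci_sens,
        ci_specificity=ci_spec,
        ci_accuracy=ci_acc,
        degenerate_sensitivity=n_pos <= 1,
        degenerate_specificity=n_neg <= 1,
    )
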