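"""Cohort statistics: summaries, group contrasts, BMI regressions, power
analysis, cumulative load and test-retest reliability.

The study design has exactly one observation per participant per outcome, so
a participant random intercept is not identifiable and the mixed-model group
contrast reduces to the pooled-variance two-sample estimator: the fixed
effect b is the difference of group means, with df = n1 + n2 - 2. That
estimator reproduces printed group mean differences exactly on exact-mean
cohorts; see the methods note for the discussion of t/p under other df
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "summarize",
    "group_compare",
    "regress",
    "sample_size",
    "cumulative_load",
    "icc_mdc",
]


@dataclass
class GroupComparison:
    b: float  # mean difference, outcome units
    se: float
    t: float
    df: float
    ci95: tuple[float, float]
    p: float
    groups: tuple[str, str]  # (reference, comparison); b = comparison - reference


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    ci95_slope: tuple[float, float]
    r_squared: float
    p: float


def summarize(values) -> dict:
    """Mean, SD and 95 % CI (t-based: mean +/- t_{0.975,n-1} SD/sqrt(n))."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return {"mean": mean, "sd": sd, "ci95": (mean - half, mean + half), "n": n}


def group_compare(values, labels, reference: str | None = None) -> GroupComparison:
    """Two-group contrast; b = mean(comparison) - mean(reference).

    Pooled-variance estimator (equivalent to the balanced fixed-effect
    model with one observation per participant). The reference group
    defaults to the first label in sorted order.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ref = reference if reference is not None else groups[0]
    if ref not in groups:
        raise ValueError(f"reference {ref!r} not among groups {groups}")
    other = groups[1] if ref == groups[0] else groups[0]
    x1, x2 = x[labels == ref], x[labels == other]
    n1, n2 = x1.size, x2.size
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least two observations")
    b = float(x2.mean() - x1.mean())
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    if se == 0.0:
        t = 0.0 if b == 0 else float(np.sign(b)) * np.inf
        p = 1.0 if b == 0 else 0.0
        half = 0.0
    else:
        t = b / se
        p = float(2.0 * sps.t.sf(abs(t), df))
        half = sps.t.ppf(0.975, df) * se
    return GroupComparison(
        b=b, se=se, t=float(t), df=float(df), ci95=(b - half, b + half), p=p,
        groups=(ref, other),
    )


def regress(predictor, outcome) -> RegressionResult:
    """Ordinary least squares of outcome on a single predictor (e.g. BMI)."""
    import statsmodels.api as sm

    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = model.conf_int()[1]
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        ci95_slope=(float(lo), float(hi)),
        r_squared=float(model.rsquared),
        p=float(model.pvalues[1]),
    )


def _power_two_sample(n: int, d: float, alpha: float) -> float:
    df = 2 * n - 2
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * np.sqrt(n / 2.0)
    return float(1.0 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size(
    mean1: float, sd1: float, mean2: float, sd2: float,
    alpha: float = 0.05, power: float = 0.80, n_max: int = 100_000,
) -> dict:
    """Smallest equal per-group n for a two-sided two-sample t-test.

    Effect size is Cohen's d with the pooled SD sqrt((sd1^2 + sd2^2)/2);
    power is evaluated exactly through the noncentral t distribution.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if mean1 == mean2:
        raise ValueError("equal means: required sample size is unbounded")
    d = abs(mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)
    n = 2
    while _power_two_sample(n, d, alpha) < power:
        n += 1
        if n > n_max:
            raise RuntimeError("sample size search exceeded cap")
    return {"d": float(d), "n_per_group": n, "n_total": 2 * n,
            "achieved_power": _power_two_sample(n, d, alpha)}


def cumulative_load(waveform, stride_length: float) -> float:
    """Mean stance-phase force divided by stride length (per-distance
    loading exposure; N/m for a waveform in N, BW/m for a normalized one)."""
    if stride_length <= 0:
        raise ValueError("stride length must be positive")
    values = np.asarray(getattr(waveform, "values", waveform), dtype=float)
    if values.size == 0:
        raise ValueError("empty waveform")
    return float(values.mean() / stride_length)


def icc_mdc(matrix) -> dict:
    """Two-way mixed-effects consistency ICC (single measures) and MDC.

    ``matrix`` is subjects x trials. ICC(3,1) from the ANOVA decomposition:
    (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error).
    MDC = 1.96 * sqrt(2) * SEM with SEM = SD * sqrt(1 - ICC), SD taken over
    all measurements.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 trials")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("degenerate matrix: zero total variance")
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_trial = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_trial
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    icc = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
    sd = x.std(ddof=1)
    sem = sd * np.sqrt(max(1.0 - icc, 0.0))
    return {"icc": float(icc), "sem": float(sem),
            "mdc": float(1.96 * np.sqrt(2.0) * sem)}
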