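"""Statistical toolkit used across the analysis.

Welch and paired t-tests compare means across cohorts and across trial
types; one-way repeated-measures ANOVA tests condition effects within a
cohort; Benjamini-Hochberg controls the false discovery rate across a
comparison family; Theil–Sen regression provides outlier-insensitive
slopes, with slope inference from a seeded bootstrap.

Thin wrappers around scipy/statsmodels where those implement the test;
the repeated-measures decomposition and the Theil–Sen bootstrap inference
are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float
    degenerate: bool = False


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_p: float
    pearson_r: float
    n: int
    slope_se: float = np.nan
    slope_ci: tuple[float, float] = (np.nan, np.nan)


# ---------------------------------------------------------------------------
# t-tests


def welch_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Welch's two-sample t-test from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with Welch–Satterthwaite
    degrees of freedom; two-tailed p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        return TestResult("welch_t", 0.0, float(n1 + n2 - 2), 1.0, degenerate=True)
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("welch_t", float(t), float(df), float(p))


def welch_t(x, y) -> TestResult:
    """Welch's t-test from raw samples (equivalent to the summary form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_from_stats(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def paired_t(x, y) -> TestResult:
    """Two-tailed paired t-test (one-sample t on the differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return _one_sample(x - y, 0.0, "paired_t")


def one_sample_t(x, mu0: float = 0.0) -> TestResult:
    """One-sample two-tailed t-test against mu0."""
    return _one_sample(np.asarray(x, dtype=float), mu0, "one_sample_t")


def _one_sample(d: np.ndarray, mu0: float, name: str) -> TestResult:
    if d.size < 2:
        raise ValueError("need n >= 2")
    sd = d.std(ddof=1)
    df = float(d.size - 1)
    if sd == 0:
        return TestResult(name, 0.0, df, 1.0, degenerate=True)
    t = (d.mean() - mu0) / (sd / np.sqrt(d.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(name, float(t), df, float(p))


# ---------------------------------------------------------------------------
# multiple comparisons


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control over one comparison family.

    Returns (adjusted p-values, boolean rejection mask at level q).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# robust regression


def theil_sen(
    x, y, n_boot: int = 1000, seed: int | np.random.Generator | None = 0
) -> RegressionResult:
    """Theil–Sen regression: slope = median of all pairwise slopes.

    The intercept is ``median(y - slope * x)``. Slope inference uses a
    seeded bootstrap over observations: the reported two-tailed p comes
    from t = slope / SD_boot(slope) with n - 2 degrees of freedom, testing
    the slope against zero. Pearson's r is reported alongside (it is
    orientation- and scale-free).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("all x equal: slope undefined")
    with np.errstate(invalid="ignore"):
        slope = float(sps.theilslopes(y, x).slope)
        intercept = float(np.median(y - slope * x))
        r = float(sps.pearsonr(x, y).statistic) if np.ptp(y) > 0 else 0.0

        rng = np.random.default_rng(seed)
        n = x.size
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            while np.ptp(x[idx]) == 0:
                idx = rng.integers(0, n, n)
            boots[b] = sps.theilslopes(y[idx], x[idx]).slope
    se = float(boots.std(ddof=1))
    if se == 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        p = float(2.0 * sps.t.sf(abs(slope) / se, n - 2))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return RegressionResult(slope, intercept, p, r, n, slope_se=se, slope_ci=ci)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def rm_anova_oneway(data) -> AnovaResult:
    """One-way repeated-measures ANOVA on an (n_subjects, k_conditions) matrix.

    Standard within-subject decomposition: the condition effect is tested
    against the subject-by-condition residual, df = (k-1, (k-1)(n-1)).
    No sphericity correction is applied.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a complete (n>=2) x (k>=2) matrix")
    if np.any(np.isnan(data)):
        raise ValueError("missing cells are not supported")
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        return AnovaResult(0.0 if ms_cond == 0 else np.inf, df1, df2,
                           1.0 if ms_cond == 0 else 0.0)
    F = ms_cond / ms_err
    return AnovaResult(float(F), df1, df2, float(sps.f.sf(F, df1, df2)))
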