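"""Method-agreement and reliability statistics.

Implements the validation toolkit for comparing device-derived cycle times
against a reference (video annotation): Pearson/Spearman correlation, paired
t test, Bland–Altman bias and 95 % limits of agreement (LoA) with confidence
bands, single-rater intraclass correlations ICC(2,1) (two-way random effects,
absolute agreement) and ICC(3,1) (two-way mixed, consistency), macro-averaged
F1 for strategy labels, and a random-intercept linear mixed model for
per-cycle differences nested in participants, from which nesting-aware LoA
follow as ``beta0 ± 1.96 * sqrt(sigma_between² + sigma_within²)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import f1_score
import statsmodels.api as sm

from .errors import DataError


@dataclass
class PairedMeasurements:
    """Participant-level paired values from two measurement methods."""

    unit_ids: list
    method_a: np.ndarray
    method_b: np.ndarray

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if not (len(self.unit_ids) == self.method_a.size == self.method_b.size):
            raise DataError("unit_ids and both methods must have equal length")

    @property
    def n(self) -> int:
        return self.method_a.size

    @property
    def differences(self) -> np.ndarray:
        return self.method_a - self.method_b


@dataclass
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    n: int


@dataclass
class Correlations:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    t_stat: float
    p_value: float
    mae: float


@dataclass
class AgreementReport:
    """Full participant-level agreement summary between two methods."""

    pearson_r: float
    spearman_rho: float
    t_stat: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    icc_2_1: float
    icc_3_1: float
    mae: float
    n: int


@dataclass
class LmmFit:
    """Random-intercept model fit for per-cycle method differences."""

    beta0: float
    sigma_between: float
    sigma_within: float
    p_method_effect: float
    nested_loa: tuple[float, float]
    n_units: int
    n_obs: int


def bland_altman(pairs: PairedMeasurements) -> BlandAltman:
    """Bias, ±1.96·SD limits of agreement and their 95 % CIs.

    The LoA standard error uses the conventional ``sqrt(3/n)·SD``
    approximation.
    """
    if pairs.n < 3:
        raise DataError("Bland-Altman needs at least 3 paired units")
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    se_loa = np.sqrt(3.0 / pairs.n) * sd
    return BlandAltman(bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
                       loa_low_ci=(lo - 1.96 * se_loa, lo + 1.96 * se_loa),
                       loa_high_ci=(hi - 1.96 * se_loa, hi + 1.96 * se_loa),
                       n=pairs.n)


def correlations_and_t(pairs: PairedMeasurements) -> Correlations:
    """Pearson and Spearman correlation plus two-sided paired t test."""
    if pairs.n < 3:
        raise DataError("correlation needs at least 3 paired units")
    a, b = pairs.method_a, pairs.method_b
    if a.std() == 0 or b.std() == 0:
        raise DataError("zero variance in one method; correlation undefined")
    pr = sstats.pearsonr(a, b)
    sr = sstats.spearmanr(a, b)
    if np.allclose(a, b):
        t_stat, p = 0.0, 1.0  # identical methods: no testable difference
    else:
        tt = sstats.ttest_rel(a, b)
        t_stat, p = float(tt.statistic), float(tt.pvalue)
    mae = float(np.abs(pairs.differences).mean())
    return Correlations(pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
                        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
                        t_stat=t_stat, p_value=p, mae=mae)


def icc(ratings: np.ndarray, form: str = "2_1") -> float:
    """Single-rater ICC from the two-way ANOVA mean squares.

    ``ratings`` is an ``(n_units, k_methods)`` matrix with no missing cells.
    Form ``"2_1"`` is two-way random effects, absolute agreement; ``"3_1"``
    two-way mixed, consistency.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise DataError("ICC needs an (n >= 3, k >= 2) matrix")
    if not np.isfinite(x).all():
        raise DataError("ICC matrix has missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    if msr <= mse:
        warnings.warn("between-unit variance does not exceed error variance; "
                      "ICC estimate is unstable", stacklevel=2)
    if form == "2_1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form == "3_1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("form must be '2_1' or '3_1'")
    return float((msr - mse) / denom)


def macro_f1(truth: list[str], predicted: list[str]) -> float:
    """Unweighted mean of per-class F1 over the classes present in either
    truth or prediction; a class absent from both is excluded."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    labels = sorted(set(truth) | set(predicted))
    return float(f1_score(truth, predicted, labels=labels, average="macro",
                          zero_division=0))


def fit_random_intercept_lmm(diffs: np.ndarray, unit_ids) -> LmmFit:
    """REML fit of ``d_ij = beta0 + u_i + eps_ij`` with participant intercepts.

    Returns the fixed bias, between-/within-participant standard deviations,
    the Wald p value for ``beta0 = 0`` and the nesting-aware LoA.  REML (not
    ML) keeps the variance components unbiased at modest unit counts;
    unbalanced designs are handled by the numeric optimiser.
    """
    d = np.asarray(diffs, dtype=float)
    units = np.asarray(unit_ids)
    if d.size != units.size:
        raise DataError("diffs and unit_ids must have equal length")
    uniq = np.unique(units)
    if uniq.size < 2:
        raise DataError("sigma_between is unidentifiable with a single unit")
    if uniq.size < 3:
        warnings.warn("fewer than 3 units; variance components are fragile",
                      stacklevel=2)
    if np.allclose(d, d[0]):
        # all differences identical: bias is exact, both variances vanish
        return LmmFit(beta0=float(d[0]), sigma_between=0.0, sigma_within=0.0,
                      p_method_effect=0.0 if d[0] != 0 else 1.0,
                      nested_loa=(float(d[0]), float(d[0])),
                      n_units=int(uniq.size), n_obs=int(d.size))
    model = sm.MixedLM(endog=d, exog=np.ones((d.size, 1)), groups=units)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    beta0 = float(np.asarray(fit.fe_params)[0])
    sigma_b = float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))
    sigma_w = float(np.sqrt(fit.scale))
    if sigma_w == 0:
        warnings.warn("zero residual variance; degenerate fit", stacklevel=2)
    p = float(np.asarray(fit.pvalues)[0])
    half = 1.96 * float(np.hypot(sigma_b, sigma_w))
    return LmmFit(beta0=beta0, sigma_between=sigma_b, sigma_within=sigma_w,
                  p_method_effect=p, nested_loa=(beta0 - half, beta0 + half),
                  n_units=int(uniq.size), n_obs=int(d.size))


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    """Compose correlations, paired t, Bland–Altman and both ICC forms."""
    ba = bland_altman(pairs)
    corr = correlations_and_t(pairs)
    matrix = np.column_stack([pairs.method_a, pairs.method_b])
    return AgreementReport(
        pearson_r=corr.pearson_r, spearman_rho=corr.spearman_rho,
        t_stat=corr.t_stat, p_value=corr.p_value,
        bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
        loa_low_ci=ba.loa_low_ci, loa_high_ci=ba.loa_high_ci,
        icc_2_1=icc(matrix, "2_1"), icc_3_1=icc(matrix, "3_1"),
        mae=corr.mae, n=pairs.n)
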