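"""Cohort-level statistics.

Descriptives are medians with interquartile ranges (the paired measurements
are not normally distributed); paired position comparisons use the Wilcoxon
signed-rank test; dichotomized Likert frequencies are compared with a Fisher
exact test; two-rater ordinal agreement uses Gwet's AC2 with quadratic
weights (Gwet 2008), which is robust to prevalence imbalance where Cohen's
kappa is not; and the air-volume threshold ``V_thresh-air`` is the volume at
predicted probability 0.5 of a univariate logistic model linking supine
proximal air volume to the "appreciable air" judgement (Likert >= 4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

#: Interpretation bands for chance-corrected agreement coefficients.
AGREEMENT_BENCHMARKS = [
    (-1.00, 0.00, "poor"),
    (0.00, 0.20, "slight"),
    (0.21, 0.40, "fair"),
    (0.41, 0.60, "moderate"),
    (0.61, 0.80, "substantial"),
    (0.81, 1.00, "almost perfect"),
]


def interpret_agreement(value: float) -> str:
    """Map an agreement coefficient onto its verbal benchmark band."""
    if value < 0.0:
        return "poor"
    for lo, hi, name in AGREEMENT_BENCHMARKS[1:]:
        if value <= hi:
            return name
    return "almost perfect"


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (linear-interpolation convention) of finite values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    method: str


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original convention).  The exact
    null distribution is used for n <= 25 without ties in |d|; otherwise the
    normal approximation with continuity (and tie) correction.  If every
    difference is zero the test is vacuous and p = 1 is returned with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", RuntimeWarning,
                      stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method=method)
    return WilcoxonResult(float(res.statistic), float(min(res.pvalue, 1.0)), n, method)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood summation) for a
    2x2 table of nonnegative integer counts."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table must contain nonnegative integers")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


@dataclass
class GwetResult:
    coefficient: float
    p_observed: float
    p_expected: float
    n_subjects: int
    categories: list
    benchmark: str = ""

    def __post_init__(self) -> None:
        self.benchmark = interpret_agreement(self.coefficient)


def gwet_ac2(ratings, categories=None) -> GwetResult:
    """Gwet's AC2 chance-corrected agreement for two raters, quadratic weights.

    Parameters
    ----------
    ratings : (n_subjects, 2) array-like
        One ordinal rating per rater per subject.
    categories : sequence, optional
        The full ordinal scale (sorted).  Defaults to the values observed in
        the data; pass the declared scale when some categories are unused.

    Notes
    -----
    With quadratic weights ``w_kl = 1 - (k - l)^2 / (q - 1)^2``, observed
    agreement is the mean weighted agreement across subjects and chance
    agreement is ``p_e = T_w / (q (q - 1)) * sum_k pi_k (1 - pi_k)`` where
    ``T_w`` is the sum of all weights and ``pi_k`` the category propensity
    averaged over raters (Gwet 2008).
    """
    arr = np.asarray(ratings)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("ratings must be an (n_subjects, 2) array; exactly "
                         "two raters are supported")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    if categories is None:
        categories = np.unique(arr)
    categories = np.asarray(sorted(categories))
    q = categories.size
    if q < 2:
        raise ValueError("the ordinal scale needs at least two categories")
    index = {c: i for i, c in enumerate(categories.tolist())}
    try:
        r1 = np.array([index[v] for v in arr[:, 0].tolist()])
        r2 = np.array([index[v] for v in arr[:, 1].tolist()])
    except KeyError as exc:
        raise ValueError(f"rating {exc} outside the declared scale") from exc

    k = np.arange(q)
    weights = 1.0 - (k[:, None] - k[None, :]) ** 2 / (q - 1) ** 2
    p_a = float(np.mean(weights[r1, r2]))
    pi = (np.bincount(r1, minlength=q) + np.bincount(r2, minlength=q)) / (2.0 * n)
    t_w = float(weights.sum())
    p_e = t_w / (q * (q - 1)) * float(np.sum(pi * (1.0 - pi)))
    ac2 = (p_a - p_e) / (1.0 - p_e)
    return GwetResult(float(ac2), p_a, p_e, n, categories.tolist())


@dataclass
class LogisticThresholdResult:
    """Air-volume threshold from a univariate logistic model.

    ``v_thresh_air`` is the volume at predicted probability 0.5, i.e.
    ``-beta0 / beta1``; under perfect separation the midpoint between the
    class-extreme volumes is reported instead with ``separated=True``.
    """

    v_thresh_air: float
    beta0: float | None
    beta1: float | None
    p_value: float | None
    n: int
    separated: bool = False


def logistic_air_threshold(air_cm3, appreciable) -> LogisticThresholdResult:
    """Fit P(appreciable) = sigmoid(b0 + b1 * air) and return ``V_thresh-air``.

    Requires both outcome classes and n >= 10; refuses a non-increasing fit
    (b1 <= 0).  Perfect separation is reported as the midpoint between the
    largest negative-class and smallest positive-class volume.
    """
    air = np.asarray(air_cm3, dtype=float)
    y = np.asarray(appreciable, dtype=int)
    if air.shape != y.shape:
        raise ValueError("air volumes and labels must have equal length")
    n = air.size
    if n < 10:
        raise ValueError("logistic threshold estimation needs n >= 10")
    if not (0 < y.sum() < n):
        raise DegenerateInputError("both outcome classes must be present")
    hi_neg = air[y == 0].max()
    lo_pos = air[y == 1].min()
    if lo_pos > hi_neg:  # perfect separation: likelihood diverges
        return LogisticThresholdResult(float((hi_neg + lo_pos) / 2.0),
                                       None, None, None, n, separated=True)
    if air[y == 1].max() < air[y == 0].min():
        raise ValueError("appreciable air decreases with volume; model misspecified")
    import statsmodels.api as sm

    model = sm.Logit(y, sm.add_constant(air))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(disp=0, maxiter=200)
    beta0, beta1 = fit.params
    if beta1 <= 0:
        raise ValueError("fitted slope is non-positive; no meaningful threshold")
    return LogisticThresholdResult(float(-beta0 / beta1), float(beta0),
                                   float(beta1), float(fit.pvalues[1]), n)


@dataclass
class PairedComparison:
    """Median/IQR descriptives and paired test for one variable, both positions."""

    variable: str
    n: int
    supine_median: float
    supine_q1: float
    supine_q3: float
    prone_median: float
    prone_q1: float
    prone_q3: float
    p_value: float | None
    evaluable: bool = True

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class CohortSummary:
    """Whole-cohort and high-air-subgroup paired comparisons."""

    n: int
    v_thresh_air: float
    whole: list[PairedComparison]
    subgroup: list[PairedComparison]
    n_subgroup: int
    fisher_p_likert: float | None
    scatter: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "v_thresh_air_cm3": self.v_thresh_air,
            "n_subgroup": self.n_subgroup,
            "whole": [c.to_dict() for c in self.whole],
            "subgroup": [c.to_dict() for c in self.subgroup],
            "fisher_p_likert": self.fisher_p_likert,
        }


_PAIRED_VARIABLES = [
    ("rectal_air_prox_cm3", "air_supine_cm3", "air_prone_cm3"),
    ("distortion_post_mm", "distortion_supine_mm", "distortion_prone_mm"),
]


def _compare(df: pd.DataFrame, variable: str, sup_col: str, pro_col: str,
             min_n: int = 5) -> PairedComparison:
    sup = df[sup_col].to_numpy(float)
    pro = df[pro_col].to_numpy(float)
    n = len(df)
    if n == 0:
        return PairedComparison(variable, 0, *[float("nan")] * 6, None, False)
    sm_, s1, s3 = median_iqr(sup)
    pm_, p1, p3 = median_iqr(pro)
    if n < min_n:
        return PairedComparison(variable, n, sm_, s1, s3, pm_, p1, p3, None, False)
    if np.array_equal(sup, pro):
        p = 1.0
    else:
        p = wilcoxon_signed_rank(sup, pro).p_value
    return PairedComparison(variable, n, sm_, s1, s3, pm_, p1, p3, p, True)


def subgroup_compare(cohort: pd.DataFrame, v_thresh: float) -> CohortSummary:
    """Whole-cohort and subgroup (supine air > ``v_thresh``) paired analyses.

    Returns medians/IQRs and Wilcoxon p-values for the proximal air volume
    and the posterior distortion, the Fisher exact test on dichotomized
    Likert scores, and the long-format air-vs-distortion scatter table.
    Subgroups smaller than 5 patients are reported as not evaluable.
    """
    whole = [_compare(cohort, v, s, p) for v, s, p in _PAIRED_VARIABLES]
    sub_df = cohort[cohort["air_supine_cm3"] > v_thresh]
    subgroup = [_compare(sub_df, v, s, p) for v, s, p in _PAIRED_VARIABLES]
    fisher_p = None
    if {"likert_supine", "likert_prone"} <= set(cohort.columns) and len(cohort):
        sup_hi = int((cohort["likert_supine"] >= 4).sum())
        pro_hi = int((cohort["likert_prone"] >= 4).sum())
        n = len(cohort)
        fisher_p = fisher_exact_2x2(
            np.array([[sup_hi, n - sup_hi], [pro_hi, n - pro_hi]]))
    scatter = pd.concat([
        pd.DataFrame({
            "patient_id": cohort["patient_id"],
            "position": pos,
            "air_cm3": cohort[f"air_{pos}_cm3"],
            "distortion_mm": cohort[f"distortion_{pos}_mm"],
        })
        for pos in ("supine", "prone")
    ], ignore_index=True)
    return CohortSummary(len(cohort), float(v_thresh), whole, subgroup,
                         len(sub_df), fisher_p, scatter)


__all__ = [
    "AGREEMENT_BENCHMARKS",
    "interpret_agreement",
    "median_iqr",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "fisher_exact_2x2",
    "GwetResult",
    "gwet_ac2",
    "LogisticThresholdResult",
    "logistic_air_threshold",
    "PairedComparison",
    "CohortSummary",
    "subgroup_compare",
]
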