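"""Predictive-performance evaluation of genetic risk scores.

ROC curves with trapezoidal AUC, DeLong variance and confidence intervals,
the paired DeLong test for correlated ROC curves (comparing nested genetic
models scored on the same samples), the Youden-optimal threshold, the
Mann-Whitney comparison of case and control score distributions, and
prevalence-adjusted predictive values.

Orientation is fixed by contract: higher score = more case-like. A sample is
called positive when its score is >= the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .genotypes import CASE, CONTROL
from .population_sim import Z95

__all__ = [
    "ROCResult",
    "roc_curve",
    "delong_auc_ci",
    "delong_paired_test",
    "best_threshold",
    "mann_whitney",
    "predictive_values",
]


@dataclass
class ROCResult:
    """ROC operating points (thresholds ascending) plus AUC and DeLong CI.

    ``sens`` is non-increasing and ``spec`` non-decreasing in the threshold;
    the AUC equals the trapezoidal area of the (1-spec, sens) polyline.
    ``auc_var`` and the CI are NaN when either class has fewer than two
    samples.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_var: float
    ci_low: float
    ci_high: float


def _binary_labels(labels) -> np.ndarray:
    """Coerce labels to a boolean case indicator."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        values = set(labels.tolist())
        if not values <= {CASE, CONTROL}:
            raise ValueError(f"labels must be '{CASE}'/'{CONTROL}', got {sorted(values)}")
        return labels == CASE
    return labels.astype(bool)


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    is_case = _binary_labels(labels)
    if scores.shape != is_case.shape:
        raise ValueError("scores and labels must have the same length")
    cases, controls = scores[is_case], scores[~is_case]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def _delong_placements(cases: np.ndarray, controls: np.ndarray):
    """Midrank placement values of the DeLong decomposition.

    Returns ``(auc, v_case, v_control)`` where ``v_case[i]`` is the fraction
    of controls scored below case i (ties counted half) and symmetrically for
    ``v_control``; the AUC is the mean placement, i.e. the midrank
    Mann-Whitney probability P(case > control) + 0.5 P(tie).
    """
    m, n = cases.size, controls.size
    combined = np.concatenate([cases, controls])
    rz = stats.rankdata(combined)
    v_case = (rz[:m] - stats.rankdata(cases)) / n
    v_control = 1.0 - (rz[m:] - stats.rankdata(controls)) / m
    return float(v_case.mean()), v_case, v_control


def roc_curve(scores, labels) -> ROCResult:
    """ROC of a score against case/control labels.

    One operating point per distinct score plus a sentinel at which nothing
    is called positive; AUC by the trapezoid rule, which with the
    distinct-score operating points implements the midrank tie convention.
    DeLong variance and 95% CI are filled in when both classes have at least
    two samples.
    """
    cases, controls = _split_scores(scores, labels)
    is_case = _binary_labels(labels)
    fpr, tpr, thr = _sk_roc_curve(is_case, np.asarray(scores, dtype=float), drop_intermediate=False)
    # sklearn returns thresholds descending with an +inf sentinel first.
    order = slice(None, None, -1)
    sens, spec, thresholds = tpr[order], 1.0 - fpr[order], thr[order]
    auc = float(np.trapezoid(tpr, fpr))
    auc_var = ci_low = ci_high = float("nan")
    if cases.size >= 2 and controls.size >= 2:
        auc_var, ci_low, ci_high = _delong_var_ci(auc, cases, controls)
    return ROCResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        auc_var=auc_var,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def _delong_var_ci(auc: float, cases: np.ndarray, controls: np.ndarray):
    _, v_case, v_control = _delong_placements(cases, controls)
    var = v_case.var(ddof=1) / cases.size + v_control.var(ddof=1) / controls.size
    half = Z95 * np.sqrt(var)
    return float(var), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def delong_auc_ci(roc: ROCResult, scores, labels) -> tuple[float, float, float]:
    """DeLong (placement-value) AUC variance and truncated 95% CI."""
    cases, controls = _split_scores(scores, labels)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("DeLong variance requires at least two samples per class")
    return _delong_var_ci(roc.auc, cases, controls)


def delong_paired_test(scores_model_a, scores_model_b, labels) -> tuple[float, float]:
    """Paired DeLong test of two AUCs computed on the same samples.

    ``z = (aucA - aucB) / sqrt(varA + varB - 2 cov)`` with the covariance
    from paired placement values; two-sided normal p. Returns ``(z, p)``;
    identical score vectors give ``(0, 1)``.
    """
    a = np.asarray(scores_model_a, dtype=float)
    b = np.asarray(scores_model_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have the same length")
    cases_a, controls_a = _split_scores(a, labels)
    cases_b, controls_b = _split_scores(b, labels)
    m, n = cases_a.size, controls_a.size
    if m < 2 or n < 2:
        raise ValueError("DeLong test requires at least two samples per class")
    auc_a, vca, vka = _delong_placements(cases_a, controls_a)
    auc_b, vcb, vkb = _delong_placements(cases_b, controls_b)
    var_a = vca.var(ddof=1) / m + vka.var(ddof=1) / n
    var_b = vcb.var(ddof=1) / m + vkb.var(ddof=1) / n
    cov = np.cov(vca, vcb, ddof=1)[0, 1] / m + np.cov(vka, vkb, ddof=1)[0, 1] / n
    denom = var_a + var_b - 2.0 * cov
    if denom <= 0.0:
        # Degenerate: no sampling variability in the AUC difference.
        if auc_a == auc_b:
            return 0.0, 1.0
        return float(np.sign(auc_a - auc_b) * np.inf), 0.0
    z = (auc_a - auc_b) / np.sqrt(denom)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def best_threshold(roc: ROCResult) -> tuple[float, float, float]:
    """Youden-optimal operating point: maximize sensitivity + specificity.

    Ties are broken by higher specificity, then lower threshold. Returns
    ``(threshold, sensitivity, specificity)``.
    """
    j = roc.sens + roc.spec
    order = np.lexsort((roc.thresholds, -roc.spec, -j))
    k = order[0]
    return float(roc.thresholds[k]), float(roc.sens[k]), float(roc.spec[k])


def mann_whitney(scores_cases, scores_controls) -> tuple[float, float]:
    """Mann-Whitney U comparison of case vs control score distributions.

    Returns ``(U, p)`` with U counted for the cases, so that
    ``U / (n_cases * n_controls)`` equals the midrank AUC. Exact enumeration
    when both groups have <= 20 samples and no ties occur; otherwise the
    normal approximation with tie and continuity corrections. Two-sided p.
    """
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all scores identical across both groups; p set to 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and x.size <= 20 and y.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def predictive_values(sensitivity: float, specificity: float, prevalence: float):
    """Positive and negative predictive values at a given prevalence.

    Bayes' rule on the 2x2 confusion probabilities. A zero denominator yields
    NaN (undefined), never an exception.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    tp = sensitivity * prevalence
    fp = (1.0 - specificity) * (1.0 - prevalence)
    tn = specificity * (1.0 - prevalence)
    fn = (1.0 - sensitivity) * prevalence
    ppv = tp / (tp + fp) if (tp + fp) > 0.0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0.0 else float("nan")
    return ppv, npv
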