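"""Agreement and detection statistics for method comparison.

Automated (y) vs manual/reference (x) measurements are compared per chamber
with Spearman's rank correlation, Bland-Altman bias and 95% limits of
agreement, and the one-way random single-measures intraclass correlation
ICC(1,1) with the conventional qualitative bands (excellent >= 0.75, good
0.60-0.74, moderate 0.40-0.59, poor <= 0.39).  Enlargement detection from
BSA-indexed EDA is scored by ROC analysis: trapezoidal AUC (equal to the
normalized Mann-Whitney U), DeLong 95% CI, and the Youden-optimal cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)  # per-subject (x+y)/2, for plotting
    diffs: np.ndarray = field(repr=False)  # per-subject y-x


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    optimal_cutoff: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)


@dataclass
class AgreementReport:
    rho: float
    rho_p: float
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    icc_band: str
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    optimal_cutoff: float | None = None


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman's rho (mid-ranks for ties) with t-approximation p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series of n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: Spearman rho undefined")
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Bias (mean of y-x) and bias +/- 1.96 SD limits of agreement."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D series of n >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(x + y) / 2.0,
        diffs=d,
    )


def icc_band(icc: float) -> str:
    """Qualitative band of an ICC value."""
    if np.isnan(icc):
        return "undefined"
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "moderate"
    return "poor"


def icc_oneway(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """One-way random single-measures ICC(1,1) for two raters.

    Each subject i contributes k=2 measurements (x_i, y_i).  From the
    one-way ANOVA decomposition, ICC = (MSB - MSW) / (MSB + (k-1) MSW).
    Negative moment estimates are reported as-is (banded poor).  If every
    value is identical there is no variance to apportion: ICC is defined as
    1 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series of n >= 3 subjects")
    data = np.stack([x, y], axis=1)  # (n, k)
    n, k = data.shape
    subj_mean = data.mean(axis=1)
    grand = data.mean()
    ssb = k * ((subj_mean - grand) ** 2).sum()
    ssw = ((data - subj_mean[:, None]) ** 2).sum()
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb + msw == 0:
        warnings.warn("all measurements identical: ICC defined as 1")
        return 1.0, "excellent"
    icc = (msb - msw) / (msb + (k - 1) * msw)
    return float(icc), icc_band(float(icc))


def _roc_points(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FPR/TPR at every distinct-score threshold (rule: score > t is positive).

    Thresholds are midpoints between adjacent distinct scores, bracketed by
    -inf/+inf, so each one realizes a distinct confusion table.
    """
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores > t
        tpr[i] = (pred & truth).sum() / n_pos
        fpr[i] = (pred & ~truth).sum() / n_neg
    return fpr, tpr, thresholds


def _delong_ci(scores: np.ndarray, truth: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95% CI for a single AUC (placement-value variance)."""
    pos = scores[truth]
    neg = scores[~truth]
    m, n = pos.size, neg.size
    # placement values: V10_i = P(pos_i > neg) + 0.5 P(==); V01_j symmetric
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    lo, hi = auc - 1.96 * se, auc + 1.96 * se
    return float(max(lo, 0.0)), float(min(hi, 1.0))


def roc(scores: np.ndarray, truth: np.ndarray) -> RocResult:
    """ROC analysis of a continuous score against a binary ground truth.

    AUC by the trapezoidal rule over all distinct thresholds (identical to
    the normalized Mann-Whitney U with half-weight ties); optimal cut-off
    by Youden's J = sensitivity + specificity - 1, ties resolved towards
    the higher threshold (fewer positives); DeLong 95% CI.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D")
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both classes present in truth")
    fpr, tpr, thresholds = _roc_points(scores, truth)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))  # first occurrence = highest threshold
    cutoff = float(thresholds[best])
    if not np.isfinite(cutoff):
        # degenerate optimum at a bracket: fall back to the nearest data value
        cutoff = float(scores.max() if cutoff == np.inf else scores.min())
    ci = _delong_ci(scores, truth, auc)
    return RocResult(auc=auc, auc_ci=ci, optimal_cutoff=cutoff, fpr=fpr, tpr=tpr, thresholds=thresholds)


def agreement_report(
    x: np.ndarray,
    y: np.ndarray,
    detection_scores: np.ndarray | None = None,
    detection_truth: np.ndarray | None = None,
) -> AgreementReport:
    """Full method-comparison report: rho, Bland-Altman, ICC and (optionally)
    enlargement-detection ROC."""
    rho, p = spearman(x, y)
    ba = bland_altman(x, y)
    icc, band = icc_oneway(x, y)
    report = AgreementReport(
        rho=rho, rho_p=p, bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
        icc=icc, icc_band=band,
    )
    if detection_scores is not None and detection_truth is not None:
        r = roc(np.asarray(detection_scores), np.asarray(detection_truth))
        report.auc = r.auc
        report.auc_ci = r.auc_ci
        report.optimal_cutoff = r.optimal_cutoff
    return report
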