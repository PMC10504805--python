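"""Discrimination and classification metrics.

AUC is the Mann-Whitney concordance probability — ties between a case and a
control score count half — which is identical to the trapezoidal area under
the ROC curve over all distinct thresholds. The bootstrap CI is the
percentile interval over with-replacement resamples of the scored test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def _split_classes(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both outcome classes must be present")
    return scores, labels, cases, controls


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(case score > control score) + 0.5·P(tie)."""
    scores, labels, cases, controls = _split_classes(scores, labels)
    ranks = stats.rankdata(scores)  # average ranks -> half credit for ties
    n1, n0 = len(cases), len(controls)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (fpr, tpr) over all distinct score thresholds.

    Starts at (0, 0), ends at (1, 1); both coordinates are non-decreasing.
    """
    scores, labels, cases, controls = _split_classes(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # keep only the last point of each tied-score run
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / len(cases)]
    fpr = np.r_[0.0, fp[distinct] / len(controls)]
    return fpr, tpr


def roc_auc_trapezoid(scores, labels) -> float:
    """Trapezoidal area under the ROC curve (equals :func:`auc`)."""
    fpr, tpr = roc_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class BootstrapAUC:
    """Percentile-bootstrap summary of a test-set AUC."""

    mean_auc: float
    ci_lower: float
    ci_upper: float
    B: int
    aucs: np.ndarray = field(repr=False)
    n_redrawn: int = 0

    def __iter__(self):  # allow tuple unpacking (mean, lower, upper)
        return iter((self.mean_auc, self.ci_lower, self.ci_upper))


def bootstrap_auc(scores, labels, B: int = 1000, seed=None,
                  confidence: float = 0.95) -> BootstrapAUC:
    """Percentile bootstrap of the AUC over with-replacement resamples.

    Each of the `B` resamples is drawn with replacement at the full test-set
    size; a resample containing a single outcome class is re-drawn (and
    counted) so that exactly `B` AUC values enter the summary. The point
    summary is the mean of the `B` AUCs; the confidence bounds are the
    empirical 2.5th and 97.5th percentiles at the default 95% level.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scores, labels, _, _ = _split_classes(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
            n_redrawn += 1
        aucs[b] = auc(scores[idx], lab)
    if n_redrawn:
        warnings.warn(f"re-drew {n_redrawn} single-class bootstrap resamples")
    alpha = 1.0 - confidence
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapAUC(float(aucs.mean()), float(lo), float(hi), B, aucs,
                        n_redrawn)


@dataclass(frozen=True)
class ClassificationMetrics:
    """2x2 confusion table and derived proportions at a probability cutpoint."""

    cutpoint: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    @property
    def confusion(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def classification_metrics(scores, labels, cutpoint: float) -> ClassificationMetrics:
    """Confusion counts and sensitivity/specificity/PPV/NPV at a cutpoint.

    A record is predicted positive when its score is >= `cutpoint`. Metrics
    whose denominator is empty are reported as NaN rather than zero.
    """
    if not 0.0 < cutpoint < 1.0:
        raise ValueError("cutpoint must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= cutpoint
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return ClassificationMetrics(
        cutpoint=float(cutpoint), tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )
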