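"""ROC curves, AUC confidence intervals, Youden cut-offs and confusion
statistics for screening continuous indexes against a binary endpoint.

Orientation convention throughout: a *higher* score means *higher* risk,
and a subject is called positive when score >= threshold.  When a score
discriminates in the opposite direction (AUC < 0.5) a warning is issued
rather than silently flipping the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "CutoffResult",
    "roc_curve",
    "auc_ci",
    "youden_cutoff",
    "confusion_stats",
    "dichotomize",
]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray  # descending; positive = score >= threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    youden_j: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    return scores, labels


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC curve with trapezoid AUC.

    Thresholds are the midpoints between consecutive distinct sorted
    scores, bracketed by -inf and +inf sentinels, so the curve runs from
    (sens=1, spec=0) down to (sens=0, spec=1).
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # last index of each run of equal scores, descending
    block_end = np.where(np.diff(s_sorted) != 0)[0]
    distinct_desc = s_sorted[np.concatenate([block_end, [len(s_sorted) - 1]])]
    mids_desc = (distinct_desc[:-1] + distinct_desc[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], mids_desc, [-np.inf]])
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(1 - y_sorted)
    tp = np.concatenate([[0], cum_tp[block_end], [n_pos]])
    fp = np.concatenate([[0], cum_fp[block_end], [n_neg]])
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    if auc < 0.5:
        warnings.warn(f"AUC {auc:.3f} < 0.5: the score is anti-predictive under "
                      "the higher-score-is-positive orientation")
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=auc, n_pos=n_pos, n_neg=n_neg)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong (1988) AUC and its variance from placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # v10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i), likewise v01 per control
    v10 = np.array([((neg < p).sum() + 0.5 * (neg == p).sum()) / n for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(scores, labels, level: float = 0.95,
           method: str = "delong") -> tuple[float, float]:
    """Wald confidence interval for the AUC, clipped to [0, 1].

    ``method``: 'delong' (default) or 'hanley-mcneil'.
    """
    scores, labels = _validate(scores, labels)
    if method == "delong":
        auc, var = _delong_variance(scores, labels)
    elif method == "hanley-mcneil":
        auc, _ = _delong_variance(scores, labels)
        m = int(labels.sum())
        n = len(labels) - m
        q1 = auc / (2 - auc)
        q2 = 2 * auc ** 2 / (1 + auc)
        var = (auc * (1 - auc) + (m - 1) * (q1 - auc ** 2)
               + (n - 1) * (q2 - auc ** 2)) / (m * n)
    else:
        raise ValueError(f"unknown method {method!r}")
    if var <= 0.0:
        warnings.warn("degenerate AUC variance; interval collapses to the point estimate")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(auc - half, 0.0), min(auc + half, 1.0)


def youden_cutoff(roc: ROCResult, scores=None, labels=None) -> CutoffResult:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the lowest finite cutoff (the most sensitive
    rule).  Confusion counts are reported when the raw scores/labels are
    supplied; otherwise they are reconstructed from the class sizes.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j.max()
    # thresholds are descending: the last argmax is the lowest (most
    # sensitive) cutoff; the ±inf sentinels are admissible, so a score
    # with no discriminating value yields J = 0 at a degenerate rule
    idx = np.where(j == best_j)[0][-1]
    cutoff = float(roc.thresholds[idx])
    if best_j <= 0.0:
        warnings.warn(f"best Youden J = {best_j:.3f} <= 0: score carries no "
                      "positive discriminating information")
    if scores is not None and labels is not None:
        scores, labels = _validate(scores, labels)
        flags = scores >= cutoff  # cutoff may be a ±inf sentinel here
        tp = int(np.sum(flags & (labels == 1)))
        fp = int(np.sum(flags & (labels == 0)))
        fn = int(np.sum(~flags & (labels == 1)))
        tn = int(np.sum(~flags & (labels == 0)))
    else:
        tp = int(round(roc.sensitivity[idx] * roc.n_pos))
        fn = roc.n_pos - tp
        tn = int(round(roc.specificity[idx] * roc.n_neg))
        fp = roc.n_neg - tn
    rates = confusion_stats(tp, fp, tn, fn)
    return CutoffResult(cutoff=cutoff, youden_j=float(best_j),
                        tp=tp, fp=fp, tn=tn, fn=fn, **rates)


def confusion_stats(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV and NPV from a 2x2 confusion table.

    Undefined ratios (empty predicted class) are reported as None, never 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both true classes must be non-empty")
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp > 0 else None,
        "npv": tn / (tn + fn) if tn + fn > 0 else None,
    }


def dichotomize(scores, cutoff: float) -> np.ndarray:
    """Boolean flags: score >= cutoff (boundary inclusive)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return np.asarray(scores, dtype=float) >= cutoff
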