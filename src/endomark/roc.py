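"""ROC curves of biomarker expression against pCR, AUC, and optimal cutoff.

Thresholds are midpoints between consecutive distinct scores plus ±infinity
endpoints; a positive call is score ≥ threshold (higher expression predicts
response, and an AUC below 0.5 is reported as-is rather than flipped).  AUC
is the trapezoidal area, which equals the Mann–Whitney U statistic divided by
n_pos·n_neg with ties counted one half.  The optimal cutoff maximizes the
Youden index J = sensitivity + specificity − 1 over the finite midpoint
thresholds, with ties broken toward the smallest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ROCCurve", "roc_curve", "optimal_cutoff"]


@dataclass
class ROCCurve:
    points: pd.DataFrame  # columns: threshold, sensitivity, specificity
    auc: float
    n_pos: int
    n_neg: int


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve of continuous scores against binary labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([np.sum(y & (s >= t)) / n_pos for t in thresholds])
    spec = np.array([np.sum(~y & (s < t)) / n_neg for t in thresholds])
    points = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ties on FPR ordered by ascending sensitivity
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCCurve(points=points, auc=auc, n_pos=n_pos, n_neg=n_neg)


def optimal_cutoff(curve: ROCCurve) -> float:
    """Threshold maximizing the Youden index over finite thresholds."""
    pts = curve.points
    finite = pts[np.isfinite(pts["threshold"])]
    if finite.empty:
        raise ValueError("curve has no finite thresholds")
    j = finite["sensitivity"] + finite["specificity"] - 1.0
    best = j.max()
    return float(finite.loc[j >= best - 1e-15, "threshold"].min())
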