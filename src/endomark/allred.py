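"""Allred scoring of RAB5A immunohistochemistry and the PFS comparison.

The Allred score is the sum of a staining-intensity component (0 negative,
1 weak, 2 intermediate, 3 strong) and a stained-cell-proportion component
(0 none, 1 ≤1%, 2 1–10%, 3 11–33%, 4 34–66%, 5 67–100%), giving totals 0 and
2–8 (a total of 1 is unreachable because no staining forces both components
to zero).  Patients are dichotomized at scores 7–8 (High) versus 0–6 (Low)
and progression-free survival in weeks is compared between the groups with a
two-sided Mann–Whitney rank-sum test.  PFS is treated as observed, without a
censoring adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import mann_whitney

__all__ = ["AllredScore", "allred_total", "dichotomize_allred", "compare_pfs"]


@dataclass
class AllredScore:
    intensity: int
    proportion: int
    total: int


def allred_total(intensity: int, proportion: int) -> AllredScore:
    """Validate components and return the total Allred score."""
    if intensity not in range(4):
        raise ValueError("intensity must be an integer 0–3")
    if proportion not in range(6):
        raise ValueError("proportion must be an integer 0–5")
    if (proportion == 0) != (intensity == 0):
        raise ValueError(
            "inconsistent components: proportion 0 and intensity 0 must co-occur"
        )
    return AllredScore(intensity=intensity, proportion=proportion, total=intensity + proportion)


def dichotomize_allred(totals, cut_high=frozenset({7, 8})) -> np.ndarray:
    """Label each total score 'High' iff it lies in ``cut_high``, else 'Low'."""
    totals = np.asarray(totals, dtype=int)
    return np.where(np.isin(totals, list(cut_high)), "High", "Low")


def compare_pfs(groups, pfs_weeks) -> dict:
    """Mann–Whitney comparison of PFS between High and Low Allred groups.

    Returns the U statistic (High as first sample), the two-sided p, and the
    per-group medians and sizes.
    """
    groups = np.asarray(groups)
    pfs = np.asarray(pfs_weeks, dtype=float)
    high = pfs[groups == "High"]
    low = pfs[groups == "Low"]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both Allred groups must be non-empty")
    u, p = mann_whitney(high, low)
    return {
        "U": u,
        "p": p,
        "median_high": float(np.median(high)),
        "median_low": float(np.median(low)),
        "n_high": int(len(high)),
        "n_low": int(len(low)),
    }
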