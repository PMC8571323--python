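"""Monte-Carlo 2-fold cross-validated biomarker threshold selection.

Procedure: for each of ``n_iterations`` iterations, half of the cohort is
drawn as training set with balance on treatment arm and pCR status.  Every
unique training expression value between the 10th and 90th percentile is a
candidate threshold; each candidate dichotomizes the training set into Low
(x < t) and High (x ≥ t) groups and the likelihood-ratio p-value of the
group×treatment interaction in the logistic model pCR ~ group + arm +
group×arm is computed.  The training-p-minimizing threshold dichotomizes the
held-out half and the test-set interaction p is recorded.  Test p-values are
grouped by selected threshold and combined with the logit method; the
threshold with the minimum combined p is selected.  The logit combination of
all test-set p-values (``overall_p``) is the procedure-level significance and
is exact-level under the null, unlike the per-threshold minimum, which is a
selection-biased quantity used only to pick the threshold.

The interaction model at a fixed threshold is saturated on the four
group×arm cells, so its maximized log-likelihood has a closed form from the
cell counts; only the no-interaction model needs iteration.  The scan over
candidates uses prefix sums over the expression-sorted training set, which
keeps full scans cheap even inside calibration experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "CVConfig",
    "CVIterationRecord",
    "CombinedP",
    "ThresholdSearchResult",
    "split_balanced",
    "candidate_thresholds",
    "interaction_p_at_threshold",
    "combine_logit",
    "run_cv",
]

_P_CLAMP = 1e-12


@dataclass
class CVConfig:
    n_iterations: int = 100
    percentile_window: tuple[float, float] = (10.0, 90.0)
    seed: int = 0
    min_group_size: int = 2

    def __post_init__(self) -> None:
        low, high = self.percentile_window
        if not (0 <= low < high <= 100):
            raise ValueError("percentile window must satisfy 0 ≤ low < high ≤ 100")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be ≥ 1")


@dataclass
class CVIterationRecord:
    iteration: int
    selected_threshold: float | None
    train_p: float | None
    test_p: float | None
    n_candidates_evaluated: int
    n_candidates_skipped: int


@dataclass
class CombinedP:
    """Logit-method combination of k p-values.

    t = −Σ ln(p_i/(1−p_i)) / sqrt(k·π²·(5k+2)/(3·(5k+4))), referred to the
    upper tail of Student-t with df = 5k+4 (applied as-is for k = 1).
    """

    k: int
    t_stat: float
    df: int
    p: float


@dataclass
class ThresholdSearchResult:
    iterations: list[CVIterationRecord]
    combined_p_by_threshold: dict[float, CombinedP]
    selected_threshold: float
    overall_p: CombinedP
    combination_method: str = "logit"

    def to_dict(self) -> dict:
        return {
            "selected_threshold": self.selected_threshold,
            "overall_combined_p": self.overall_p.p,
            "combination_method": self.combination_method,
            "combined_p_by_threshold": {
                str(t): c.p for t, c in self.combined_p_by_threshold.items()
            },
            "iterations": [vars(r) for r in self.iterations],
        }


def split_balanced(cohort: pd.DataFrame, rng: np.random.Generator):
    """Random half-split balanced on arm × pCR strata.

    Within each stratum, half the members (floor or ceil at random for odd
    strata) go to the training set.  Returns (train, test) DataFrames whose
    union is the cohort.
    """
    train_idx: list[np.ndarray] = []
    for _, sub in cohort.groupby(["arm", "pcr"], sort=True):
        idx = sub.index.to_numpy()
        perm = rng.permutation(len(idx))
        n_train = len(idx) // 2
        if len(idx) % 2 == 1 and rng.random() < 0.5:
            n_train += 1
        if len(idx) < 2:
            warnings.warn("stratum with a single member assigned at random")
        train_idx.append(idx[perm[:n_train]])
    chosen = np.concatenate(train_idx) if train_idx else np.array([], dtype=int)
    mask = cohort.index.isin(chosen)
    return cohort[mask], cohort[~mask]


def candidate_thresholds(
    train_expression, window: tuple[float, float] = (10.0, 90.0)
) -> np.ndarray:
    """Unique observed values within the percentile window, ascending.

    Percentiles use linear interpolation.  Fewer than 2 candidates (e.g. all
    values identical) is an error.
    """
    x = np.asarray(train_expression, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 training values")
    lo, hi = np.percentile(x, list(window))
    cand = np.unique(x[(x >= lo) & (x <= hi)])
    if len(cand) < 2:
        raise ValueError("fewer than 2 candidate thresholds in the window")
    return cand


def _saturated_loglik(y: np.ndarray, n: np.ndarray) -> float:
    """Binomial log-likelihood at the per-cell MLE, with 0·log 0 = 0."""
    ll = 0.0
    for yi, ni in zip(y, n):
        if ni == 0:
            continue
        p = yi / ni
        if 0 < p < 1:
            ll += yi * np.log(p) + (ni - yi) * np.log1p(-p)
    return ll


# Reduced (no-interaction) design over the 4 cells ordered
# (low,ctrl), (low,exp), (high,ctrl), (high,exp): intercept, group, arm.
_X_REDUCED = np.array(
    [[1.0, 0.0, 0.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0], [1.0, 1.0, 1.0]]
)


def _reduced_loglik(y: np.ndarray, n: np.ndarray) -> float | None:
    """Newton fit of pCR ~ group + arm on aggregated cells; None if unstable."""
    beta = np.zeros(3)
    ll_old = -np.inf
    for _ in range(60):
        mu = expit(_X_REDUCED @ beta)
        w = n * mu * (1.0 - mu)
        score = _X_REDUCED.T @ (y - n * mu)
        info = (_X_REDUCED * w[:, None]).T @ _X_REDUCED
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return None
        beta = beta + delta
        mu = np.clip(expit(_X_REDUCED @ beta), 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(mu) + (n - y) * np.log1p(-mu)))
        if abs(ll - ll_old) < 1e-10:
            if np.max(np.abs(beta)) > 15.0:
                return None
            return ll
        ll_old = ll
    return None


def _interaction_lr_p(y: np.ndarray, n: np.ndarray) -> float | None:
    ll_red = _reduced_loglik(y, n)
    if ll_red is None:
        return None
    stat = max(0.0, 2.0 * (_saturated_loglik(y, n) - ll_red))
    return float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0


def interaction_p_at_threshold(
    data: pd.DataFrame,
    threshold: float,
    arms: tuple[str, str] = ("TDM1P", "TH"),
    marker: str = "RAB5A",
    min_group_size: int = 2,
) -> float | None:
    """LR p for the group×treatment interaction at one dichotomizing threshold.

    Low means x < threshold.  Returns None (candidate skipped) when any
    arm×group cell has fewer than ``min_group_size`` members or the
    no-interaction fit is unstable.
    """
    experimental, control = arms
    sub = data[data["arm"].isin(arms)]
    x = sub[marker].to_numpy(dtype=float)
    is_exp = (sub["arm"] == experimental).to_numpy()
    pcr = sub["pcr"].to_numpy(dtype=bool)
    high = x >= threshold
    n = np.array(
        [
            np.sum(~high & ~is_exp),
            np.sum(~high & is_exp),
            np.sum(high & ~is_exp),
            np.sum(high & is_exp),
        ],
        dtype=float,
    )
    if np.any(n < min_group_size):
        return None
    y = np.array(
        [
            np.sum(pcr & ~high & ~is_exp),
            np.sum(pcr & ~high & is_exp),
            np.sum(pcr & high & ~is_exp),
            np.sum(pcr & high & is_exp),
        ],
        dtype=float,
    )
    return _interaction_lr_p(y, n)


def combine_logit(pvalues) -> CombinedP:
    """Combine p-values by the logit method.

    p-values at 0 or 1 are clamped to [1e-12, 1−1e-12] with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) < 1:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values at 0 or 1 clamped for the logit combination")
        p = np.clip(p, _P_CLAMP, 1 - _P_CLAMP)
    k = len(p)
    scale = np.sqrt(k * np.pi**2 * (5 * k + 2) / (3.0 * (5 * k + 4)))
    t_stat = float(-np.sum(np.log(p / (1.0 - p))) / scale)
    df = 5 * k + 4
    return CombinedP(k=k, t_stat=t_stat, df=df, p=float(stats.t.sf(t_stat, df)))


def _scan_train(
    x: np.ndarray,
    is_exp: np.ndarray,
    pcr: np.ndarray,
    candidates: np.ndarray,
    min_group_size: int,
):
    """Interaction LR p at every candidate threshold via prefix sums.

    Returns (pvalues, n_skipped); skipped candidates carry NaN.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    e = is_exp[order].astype(int)
    y = pcr[order].astype(int)
    cum_e = np.concatenate([[0], np.cumsum(e)])
    cum_c = np.concatenate([[0], np.cumsum(1 - e)])
    cum_ye = np.concatenate([[0], np.cumsum(y * e)])
    cum_yc = np.concatenate([[0], np.cumsum(y * (1 - e))])
    pos = np.searchsorted(xs, candidates, side="left")  # members with x < t
    total_e, total_c = cum_e[-1], cum_c[-1]
    total_ye, total_yc = cum_ye[-1], cum_yc[-1]
    ps = np.full(len(candidates), np.nan)
    n_skipped = 0
    for i, k in enumerate(pos):
        n = np.array(
            [cum_c[k], cum_e[k], total_c - cum_c[k], total_e - cum_e[k]], dtype=float
        )
        if np.any(n < min_group_size):
            n_skipped += 1
            continue
        yv = np.array(
            [cum_yc[k], cum_ye[k], total_yc - cum_yc[k], total_ye - cum_ye[k]],
            dtype=float,
        )
        p = _interaction_lr_p(yv, n)
        if p is None:
            n_skipped += 1
        else:
            ps[i] = p
    return ps, n_skipped


def run_cv(
    cohort: pd.DataFrame,
    marker: str = "RAB5A",
    arms: tuple[str, str] = ("TDM1P", "TH"),
    config: CVConfig | None = None,
    grouping: str = "per_threshold",
) -> ThresholdSearchResult:
    """Full Monte-Carlo 2-fold CV threshold search.

    ``grouping='per_threshold'`` (default): test p-values are pooled per
    distinct selected threshold, combined with the logit method, and the
    threshold achieving the minimum combined p wins (ties → smallest).
    ``grouping='combine_all'``: all test p-values are combined into a single
    p and the modal selected threshold wins.  Either way ``overall_p`` (the
    combination of every test p) is reported as the procedure significance.

    Rows are sorted by patient_id before any randomness so results do not
    depend on input row order.
    """
    if grouping not in ("per_threshold", "combine_all"):
        raise ValueError("grouping must be 'per_threshold' or 'combine_all'")
    config = config or CVConfig()
    experimental, control = arms
    data = cohort[cohort["arm"].isin(arms)].sort_values("patient_id").reset_index(drop=True)
    if set(data["arm"].unique()) != set(arms):
        raise ValueError(f"cohort must contain both arms {arms}")
    rng = np.random.default_rng(config.seed)
    records: list[CVIterationRecord] = []
    for it in range(config.n_iterations):
        train, test = split_balanced(data, rng)
        try:
            cands = candidate_thresholds(
                train[marker].to_numpy(dtype=float), config.percentile_window
            )
        except ValueError:
            records.append(CVIterationRecord(it, None, None, None, 0, 0))
            continue
        ps, n_skipped = _scan_train(
            train[marker].to_numpy(dtype=float),
            (train["arm"] == experimental).to_numpy(),
            train["pcr"].to_numpy(dtype=bool),
            cands,
            config.min_group_size,
        )
        valid = np.isfinite(ps)
        n_eval = int(valid.sum())
        if n_eval == 0:
            records.append(CVIterationRecord(it, None, None, None, 0, n_skipped))
            continue
        best = np.nanmin(ps)
        sel = float(cands[valid & (ps <= best + 0.0)][0])  # smallest threshold at min p
        test_p = interaction_p_at_threshold(
            test, sel, arms=arms, marker=marker, min_group_size=config.min_group_size
        )
        records.append(
            CVIterationRecord(it, sel, float(best), test_p, n_eval, n_skipped)
        )
    usable = [r for r in records if r.selected_threshold is not None and r.test_p is not None]
    if not usable:
        raise ValueError("all CV iterations were degenerate")
    all_test_ps = [r.test_p for r in usable]
    overall = combine_logit(all_test_ps)
    by_threshold: dict[float, list[float]] = {}
    for r in usable:
        by_threshold.setdefault(r.selected_threshold, []).append(r.test_p)
    combined = {t: combine_logit(ps) for t, ps in sorted(by_threshold.items())}
    if grouping == "per_threshold":
        best_p = min(c.p for c in combined.values())
        selected = min(t for t, c in combined.items() if c.p <= best_p)
    else:
        counts = {t: len(ps) for t, ps in by_threshold.items()}
        top = max(counts.values())
        selected = min(t for t, c in counts.items() if c == top)
    return ThresholdSearchResult(
        iterations=records,
        combined_p_by_threshold=combined,
        selected_threshold=selected,
        overall_p=overall,
    )
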