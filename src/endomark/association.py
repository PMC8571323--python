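"""Logistic-model association machinery for qualifying-biomarker analysis.

Associations between a continuous biomarker and pathologic complete response
(pCR) are assessed per treatment arm with logistic models; significance comes
from the likelihood-ratio (LR) statistic referred to chi-square with 1 degree
of freedom.  Biomarker-by-treatment interactions pool the experimental and
control arms.  Small exact and rank tests used for balance checks and the
IHC/PFS comparison live here too.

Coefficients are reported per 1 standard deviation of the biomarker, with the
SD computed within the analysis subset of each model (the arm for per-arm
models, the pooled two arms for interaction models).  No multiple-testing
adjustment is applied: markers are evaluated individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "AssociationResult",
    "ContingencyTable2x2",
    "fit_logistic",
    "lr_test",
    "qualify_biomarker",
    "interaction_test",
    "association_table",
    "fisher_exact_2x2",
    "mann_whitney",
]

_SEPARATION_BOUND = 15.0  # |coef| beyond this on standardized scales ⇒ separation


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit.

    ``loglik`` omits the binomial combinatorial constant for aggregated
    (trials > 1) inputs, so it cancels in likelihood-ratio comparisons and is
    identical to the Bernoulli log-likelihood when trials are all 1.
    """

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    loglik: float
    n: int
    converged: bool
    design_terms: list[str]
    diagnostic: str = ""


@dataclass
class AssociationResult:
    """One biomarker association: coefficient per SD, CI, OR, LR test."""

    coef: float
    ci95: tuple[float, float]
    odds_ratio_per_sd: float
    lr_stat: float
    p: float
    arm_or_contrast: str
    adjusted_for_hr: bool
    n: int = 0
    fit: LogisticFit | None = None


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _binom_loglik(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (n - y) * np.log1p(-mu)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    trials: np.ndarray | None = None,
    terms: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a logistic regression by iteratively reweighted least squares.

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column explicitly).
    y : successes per row; 0/1 for Bernoulli rows.
    trials : number of trials per row (default all 1, Bernoulli).
    terms : names for the p design columns.

    Returns a :class:`LogisticFit`.  Complete separation is reported via
    ``converged=False`` with a diagnostic rather than an exception; a
    rank-deficient design or constant outcome raises ``ValueError``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n_obs, p = X.shape
    trials = np.ones(n_obs) if trials is None else np.asarray(trials, dtype=float)
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    total_y = float(y.sum())
    if total_y <= 0 or total_y >= float(trials.sum()):
        raise ValueError("outcome is constant; logistic model is undefined")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    diagnostic = ""
    ll = ll_old
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        ll = _binom_loglik(y, trials, mu)
        w = trials * mu * (1.0 - mu)
        score = X.T @ (y - trials * mu)
        info = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            diagnostic = "singular information matrix (separation)"
            break
        # step-halving keeps the Newton update from overshooting
        step = 1.0
        for _ in range(20):
            cand = beta + step * delta
            ll_new = _binom_loglik(y, trials, expit(X @ cand))
            if ll_new >= ll - 1e-14:
                break
            step *= 0.5
        beta = beta + step * delta
        if abs(ll_new - ll_old) < tol:
            converged = True
            ll = ll_new
            break
        ll_old = ll_new
        ll = ll_new
    if converged and np.max(np.abs(beta)) > _SEPARATION_BOUND:
        converged = False
        diagnostic = "coefficient diverging: data are (quasi-)separated"
    if not converged and not diagnostic:
        diagnostic = "IRLS did not converge (possible separation)"

    mu = expit(X @ beta)
    w = trials * mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        ses = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        ses = np.full(p, np.nan)
    return LogisticFit(
        coefficients=dict(zip(terms, beta.tolist())),
        standard_errors=dict(zip(terms, ses.tolist())),
        loglik=ll,
        n=int(trials.sum()),
        converged=converged,
        design_terms=list(terms),
        diagnostic=diagnostic,
    )


def lr_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested logistic fits (1 df).

    The statistic 2·(ℓ_full − ℓ_reduced) is clipped at zero and referred to
    the upper tail of chi-square with 1 degree of freedom.
    """
    if not set(reduced.design_terms) < set(full.design_terms):
        raise ValueError("models are not nested")
    if len(full.design_terms) - len(reduced.design_terms) != 1:
        raise ValueError("LR test requires a 1-degree-of-freedom comparison")
    if full.n != reduced.n:
        raise ValueError("models were fitted to different data")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("biomarker has zero variance in the analysis subset")
    return (x - float(np.mean(x))) / sd


def _assoc_from_fits(
    full: LogisticFit,
    reduced: LogisticFit,
    term: str,
    label: str,
    adjust_hr: bool,
) -> AssociationResult:
    stat, p = lr_test(full, reduced)
    coef = full.coefficients[term]
    se = full.standard_errors[term]
    z = stats.norm.ppf(0.975)
    return AssociationResult(
        coef=coef,
        ci95=(coef - z * se, coef + z * se),
        odds_ratio_per_sd=float(np.exp(coef)),
        lr_stat=stat,
        p=p,
        arm_or_contrast=label,
        adjusted_for_hr=adjust_hr,
        n=full.n,
        fit=full,
    )


def qualify_biomarker(
    cohort: pd.DataFrame,
    marker: str,
    arm: str,
    adjust_hr: bool = False,
) -> AssociationResult:
    """Per-arm association of a biomarker with pCR.

    The biomarker is standardized to unit SD within the arm, so the
    coefficient (and odds ratio) is per 1 SD of expression.  The LR test
    compares the model with the biomarker term against the one without it;
    when ``adjust_hr`` the HR-status indicator is kept in both models.
    """
    sub = cohort[cohort["arm"] == arm]
    y = sub["pcr"].to_numpy(dtype=float)
    if len(sub) < 10 or y.sum() == 0 or y.sum() == len(sub):
        raise ValueError(f"arm {arm!r}: need n ≥ 10 with both outcomes present")
    z = _standardize(sub[marker].to_numpy(dtype=float))
    cols = [np.ones(len(sub))]
    terms = ["intercept"]
    if adjust_hr:
        cols.append((sub["hr_status"] == "HRneg").to_numpy(dtype=float))
        terms.append("hr_neg")
    X_reduced = np.column_stack(cols)
    X_full = np.column_stack(cols + [z])
    full = fit_logistic(X_full, y, terms=terms + [marker])
    reduced = fit_logistic(X_reduced, y, terms=terms)
    return _assoc_from_fits(full, reduced, marker, arm, adjust_hr)


def interaction_test(
    cohort: pd.DataFrame,
    marker: str,
    arms: tuple[str, str],
    adjust_hr: bool = False,
    standardize: bool = True,
) -> AssociationResult:
    """Biomarker×treatment interaction across an (experimental, control) pair.

    Fits pCR ~ marker + arm + marker×arm (+ HR) on the pooled two arms and
    LR-tests the interaction term.  With ``standardize`` (default) the marker
    is scaled to unit SD within the pooled subset; pass ``False`` to test on
    the raw expression scale.
    """
    experimental, control = arms
    sub = cohort[cohort["arm"].isin(arms)]
    present = set(sub["arm"].unique())
    if present != set(arms):
        raise ValueError(f"both arms {arms} must be present; found {sorted(present)}")
    y = sub["pcr"].to_numpy(dtype=float)
    x = sub[marker].to_numpy(dtype=float)
    if standardize:
        x = _standardize(x)
    t = (sub["arm"] == experimental).to_numpy(dtype=float)
    cols = [np.ones(len(sub)), x, t]
    terms = ["intercept", marker, "arm"]
    if adjust_hr:
        cols.append((sub["hr_status"] == "HRneg").to_numpy(dtype=float))
        terms.append("hr_neg")
    inter = f"{marker}:arm"
    X_reduced = np.column_stack(cols)
    X_full = np.column_stack(cols + [x * t])
    full = fit_logistic(X_full, y, terms=terms + [inter])
    reduced = fit_logistic(X_reduced, y, terms=terms)
    return _assoc_from_fits(
        full, reduced, inter, f"{experimental} vs {control} interaction", adjust_hr
    )


def association_table(
    cohort: pd.DataFrame,
    markers: list[str],
    arms: tuple[str, str],
    adjust_hr: bool = False,
) -> pd.DataFrame:
    """Summary rows behind the association plot: one row per marker×model.

    Models are the per-arm associations for the two arms plus their
    interaction contrast.  Columns include the coefficient (per SD), its
    sign, the OR per SD, and −log10 of the LR p-value.
    """
    if not markers:
        raise ValueError("need at least one marker")
    rows = []
    for marker in markers:
        results = [qualify_biomarker(cohort, marker, arm, adjust_hr) for arm in arms]
        results.append(interaction_test(cohort, marker, arms, adjust_hr))
        for res in results:
            rows.append(
                {
                    "marker": marker,
                    "model": res.arm_or_contrast,
                    "coef": res.coef,
                    "coef_sign": int(np.sign(res.coef)),
                    "odds_ratio_per_sd": res.odds_ratio_per_sd,
                    "lr_stat": res.lr_stat,
                    "p": res.p,
                    "neg_log10_p": -np.log10(res.p),
                    "adjusted_for_hr": adjust_hr,
                }
            )
    return pd.DataFrame(rows)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Uses the minimum-likelihood rule: sum hypergeometric probabilities of all
    tables with the observed margins whose point probability does not exceed
    the observed table's.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("a margin of the 2×2 table is zero; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann–Whitney rank-sum test, two-sided.

    The exact null distribution is used when n_x·n_y ≤ 400 and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction.  Returns (U statistic of ``x``, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
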