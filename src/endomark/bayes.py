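"""Bayesian covariate-adjusted logistic estimation of pCR probabilities.

pCR is modeled as a function of patient subtype — the cross of HR status and
the biomarker group (High/Low at a given threshold); HER2 status is constant
in an all-HER2-positive cohort and is absorbed — treatment arm, and the
subtype×treatment interaction, in the saturated parameterization

    logit P(pCR) = α_s + γ_s · 1[arm = experimental]

with independent Normal(0, 1) priors on every coefficient.  Sampling is
componentwise adaptive random-walk Metropolis: per-coordinate step sizes are
tuned toward a 40–50% acceptance rate during an adaptation phase and then
frozen, a burn-in is discarded, and ``n_keep`` draws are retained.  The prior
regularizes empty or separated cells, so no special-casing is needed there.

Arm-level pCR probabilities (overall or within a biomarker subset) are
posterior summaries of Σ_s w_s · invlogit(η_s), where the weights w_s are the
observed subtype proportions within the arm∩subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SUBTYPES",
    "BayesModelSpec",
    "SubtypeDesign",
    "PosteriorSummary",
    "build_subtype_design",
    "sample_posterior",
    "estimate_pcr",
]

SUBTYPES = (("HRpos", "high"), ("HRpos", "low"), ("HRneg", "high"), ("HRneg", "low"))


@dataclass
class BayesModelSpec:
    n_keep: int = 10000
    n_adapt: int = 1000
    n_burnin: int = 5000
    prior_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_keep, self.n_adapt, self.n_burnin) <= 0:
            raise ValueError("all chain lengths must be positive")


@dataclass
class SubtypeDesign:
    """Design for the saturated subtype×treatment model.

    ``X`` has one intercept indicator column per subtype followed by one
    treatment-interaction column per subtype (subtype indicator × arm
    indicator), so a row for subtype s in the experimental arm activates
    exactly α_s and γ_s.  ``terms`` names the 2·S coefficients.
    """

    X: np.ndarray
    y: np.ndarray
    subtype_index: np.ndarray
    is_experimental: np.ndarray
    terms: list[str]
    subtype_labels: list[str]


@dataclass
class PosteriorSummary:
    mean_prob: float
    pi95: tuple[float, float]
    n_draws: int
    subset_label: str
    arm: str


def _subtype_of(hr_status: np.ndarray, high: np.ndarray) -> np.ndarray:
    labels = {(hr, grp): i for i, (hr, grp) in enumerate(SUBTYPES)}
    grp = np.where(high, "high", "low")
    return np.array([labels[(h, g)] for h, g in zip(hr_status, grp)])


def build_subtype_design(
    cohort: pd.DataFrame,
    threshold: float,
    experimental_arm: str = "TDM1P",
    arms: tuple[str, str] = ("TDM1P", "TH"),
    marker: str = "RAB5A",
) -> SubtypeDesign:
    """Build the saturated subtype×treatment design on the two-arm cohort."""
    sub = cohort[cohort["arm"].isin(arms)].reset_index(drop=True)
    hr = sub["hr_status"].to_numpy()
    high = sub[marker].to_numpy(dtype=float) >= threshold
    s_idx = _subtype_of(hr, high)
    t = (sub["arm"] == experimental_arm).to_numpy(dtype=float)
    n, S = len(sub), len(SUBTYPES)
    X = np.zeros((n, 2 * S))
    X[np.arange(n), s_idx] = 1.0
    X[np.arange(n), S + s_idx] = t
    labels = [f"{hr}/{grp}" for hr, grp in SUBTYPES]
    terms = [f"alpha[{lab}]" for lab in labels] + [f"gamma[{lab}]" for lab in labels]
    empty = [labels[i] for i in range(S) if not np.any(s_idx == i)]
    if empty:
        warnings.warn(
            f"subtypes with no patients retained with prior-dominated coefficients: {empty}"
        )
    return SubtypeDesign(
        X=X,
        y=sub["pcr"].to_numpy(dtype=float),
        subtype_index=s_idx,
        is_experimental=t.astype(bool),
        terms=terms,
        subtype_labels=labels,
    )


def _log_posterior_terms(eta: np.ndarray, y: np.ndarray) -> float:
    # Bernoulli loglik: Σ yη − log(1+e^η), numerically via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def sample_posterior(
    spec: BayesModelSpec, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Adaptive random-walk Metropolis draws from the logistic posterior.

    Works for any design matrix (a column of all zeros gives a prior-only
    coefficient).  Returns an (n_keep, p) array of retained draws;
    deterministic given ``spec.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape if X.ndim == 2 else (len(X), 1)
    if X.ndim == 1:
        X = X[:, None]
    rng = np.random.default_rng(spec.seed)
    theta = np.zeros(p)
    eta = X @ theta
    loglik = _log_posterior_terms(eta, y) if n else 0.0
    steps = np.full(p, 0.5)
    accept = np.zeros(p)
    tries = np.zeros(p)
    total = spec.n_adapt + spec.n_burnin + spec.n_keep
    kept = np.empty((spec.n_keep, p))
    prior_var = spec.prior_sd**2
    adapt_block = 25
    for it in range(total):
        adapting = it < spec.n_adapt
        for j in range(p):
            delta = steps[j] * rng.standard_normal()
            theta_new = theta[j] + delta
            eta_new = eta + delta * X[:, j] if n else eta
            loglik_new = _log_posterior_terms(eta_new, y) if n else 0.0
            logr = (
                loglik_new
                - loglik
                - (theta_new**2 - theta[j] ** 2) / (2.0 * prior_var)
            )
            tries[j] += 1
            if np.log(rng.random()) < logr:
                theta[j] = theta_new
                eta = eta_new
                loglik = loglik_new
                accept[j] += 1
        if adapting and (it + 1) % adapt_block == 0:
            rate = accept / np.maximum(tries, 1)
            steps *= np.exp(rate - 0.45)  # nudge toward ~45% acceptance
            accept[:] = 0.0
            tries[:] = 0.0
        if it >= spec.n_adapt + spec.n_burnin:
            kept[it - spec.n_adapt - spec.n_burnin] = theta
    return kept


def estimate_pcr(
    draws: np.ndarray,
    design: SubtypeDesign,
    arm_is_experimental: bool,
    subset: str | None = None,
    arm_label: str = "",
) -> PosteriorSummary:
    """Posterior mean and central 95% interval of an arm's pCR probability.

    ``subset`` restricts to the biomarker group ('high' or 'low'); None uses
    the whole arm.  Per draw the probability is the subtype-proportion-
    weighted mixture of invlogit(α_s + γ_s·T); the weights are the observed
    subtype proportions within arm∩subset.
    """
    S = len(SUBTYPES)
    mask = design.is_experimental == bool(arm_is_experimental)
    if subset is not None:
        want_high = subset == "high"
        grp_high = np.array([SUBTYPES[i][1] == "high" for i in design.subtype_index])
        mask = mask & (grp_high == want_high)
    if not np.any(mask):
        raise ValueError("empty arm∩subset")
    idx = design.subtype_index[mask]
    w = np.bincount(idx, minlength=S).astype(float)
    w /= w.sum()
    eta = draws[:, :S] + (draws[:, S:] if arm_is_experimental else 0.0)
    probs = expit(eta) @ w
    lo, hi = np.percentile(probs, [2.5, 97.5])
    return PosteriorSummary(
        mean_prob=float(probs.mean()),
        pi95=(float(lo), float(hi)),
        n_draws=len(probs),
        subset_label=subset or "overall",
        arm=arm_label or ("experimental" if arm_is_experimental else "control"),
    )
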