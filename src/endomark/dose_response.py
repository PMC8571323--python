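"""Sigmoid viability fits, IC50 extraction, and sensitivity regression.

The viability model is v = a/(1 + exp(−(x − x0)/b)) with x = log10 of the
drug concentration: doses in these assays span roughly four decades, so the
abscissa is logarithmic.  ``a`` is the untreated asymptote (viability
fraction), ``x0`` the inflection location and ``b`` the slope scale (negative
when viability falls with dose).  IC50 is defined as the concentration at
which the fitted curve equals 0.5 of untreated viability (absolute half-max,
not half of the asymptote), so curves whose asymptote never reaches 0.5 have
no IC50.

Biomarker expression is related to sensitivity by ordinary least squares of
1/IC50 on expression; the R² is the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SigmoidFit",
    "LinearFitResult",
    "fit_sigmoid",
    "ic50_from_fit",
    "sensitivity_regression",
]


@dataclass
class SigmoidFit:
    a: float
    x0: float
    b: float
    ic50: float | None
    rss: float
    converged: bool


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r2: float
    n: int


def _model(x: np.ndarray, a: float, x0: float, b: float) -> np.ndarray:
    return a / (1.0 + np.exp(np.clip(-(x - x0) / b, -500, 500)))


def fit_sigmoid(concentrations, viabilities) -> SigmoidFit:
    """Least-squares sigmoid fit on log10 concentration, multi-start.

    Starts are a coarse grid over x0 (the observed log-dose range) and b
    (both signs, several magnitudes), each refined by Levenberg–Marquardt
    style local least squares; the best residual sum of squares wins.  The
    ``converged`` flag is honest: degenerate data (e.g. flat viability) where
    no start improves on a flat curve report ``converged=False``.
    """
    conc = np.asarray(concentrations, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    x = np.log10(conc)

    def resid(theta):
        return _model(x, *theta) - v

    a0 = max(float(np.max(v)), 1e-3)
    # data-driven start: inflection near the dose whose mean viability is
    # closest to half the top, slope sign from the dose-viability trend
    half_idx = int(np.argmin(np.abs(v - a0 / 2.0)))
    slope_sign = -1.0 if np.polyfit(x, v, 1)[0] < 0 else 1.0
    starts = [(a0, float(x[half_idx]), slope_sign * 0.5)]
    grid = [
        (a0, x0, b)
        for x0 in np.linspace(x.min(), x.max(), 5)
        for b in (-1.0, -0.3, 0.3, 1.0)
    ]
    rss_flat = float(np.sum((v - v.mean()) ** 2))
    best = None
    for i, start in enumerate(starts + grid):
        try:
            sol = optimize.least_squares(
                resid, list(start), xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
        # the data-driven start explaining ≥98% of variance ends the search
        if i == 0 and rss_flat > 0 and rss < 0.02 * rss_flat:
            break
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, None, np.inf, False)
    rss, sol = best
    a, x0, b = (float(t) for t in sol.x)
    # A fit that cannot beat the flat mean curve by a meaningful margin has
    # not identified a sigmoid (constant viability is the canonical case).
    converged = bool(sol.success) and a > 0 and rss < rss_flat - 1e-12
    fit = SigmoidFit(a=a, x0=x0, b=b, ic50=None, rss=rss, converged=converged)
    if converged and a > 0.5:
        try:
            fit.ic50 = ic50_from_fit(fit)
        except ValueError:
            fit.ic50 = None
    return fit


def ic50_from_fit(fit: SigmoidFit) -> float:
    """Concentration (µg/ml) where the fitted curve crosses viability 0.5.

    Closed form: the curve equals 0.5 at x* = x0 − b·ln(a/0.5 − 1), so
    IC50 = 10^x*.  Raises if the asymptote never reaches 0.5.
    """
    if not fit.converged:
        raise ValueError("cannot extract IC50 from a non-converged fit")
    if fit.a <= 0.5:
        raise ValueError("curve never reaches 50% viability; IC50 undefined")
    x_star = fit.x0 - fit.b * np.log(fit.a / 0.5 - 1.0)
    return float(10.0**x_star)


def sensitivity_regression(expression, ic50s) -> LinearFitResult:
    """OLS of sensitivity (1/IC50) on marker expression.

    With two points R² is 1 by construction (zero residual degrees of
    freedom); interpret accordingly.
    """
    x = np.asarray(expression, dtype=float)
    ic = np.asarray(ic50s, dtype=float)
    if len(x) != len(ic) or len(x) < 2:
        raise ValueError("need equal-length inputs with at least 2 points")
    if np.any(ic <= 0):
        raise ValueError("IC50 values must be positive")
    if np.ptp(x) == 0:
        raise ValueError("expression has zero variance")
    y = 1.0 / ic
    res = stats.linregress(x, y)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(x),
    )
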