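"""Linear discriminant analysis and the one-dimensional FDP criteria.

A two-class Fisher discriminant is fitted on the partition feature vector
with the midpoint threshold rule.  The sign convention follows the
published function: the score is positive on the non-hematuria side, so a
record is classified hematuria when its score is negative.  Substituting
the anchor regressions into the discriminant collapses it to an exactly
linear boundary on the (fibrinogen, FDP) plane.

For settings where only FDP is available, the plane probability is
evaluated along the single regression of fibrinogen on FDP and the
smallest FDP at which it crosses 0.5 becomes the one-dimensional
criterion (smaller thresholds err on the conservative, alarm-earlier
side).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .cohort import Cohort
from .partition import FactorPartition
from .projection import PlaneFunction, RegressionBundle, SimpleRegression

__all__ = [
    "DiscriminantFunction",
    "PlaneLine",
    "FdpCriterion",
    "fit_discriminant",
    "discriminant_plane_line",
    "fit_alpha_on_beta",
    "fdp_criterion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscriminantFunction:
    """Fisher linear discriminant: score = constant + sum(coef * factor).

    Positive score = non-hematuria; hematuria is called when score < 0.
    ``eta_squared`` is the correlation ratio (between-group share of the
    score's total sum of squares); ``error_probability_pct`` the
    normal-theory two-Gaussian misclassification probability (percent)
    at pooled covariance and equal priors.
    """

    constant: float
    coefficients: dict[str, float]
    eta_squared: float
    error_probability_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_squared <= 1.0):
            raise ValueError(f"eta squared out of [0, 1]: {self.eta_squared}")

    @property
    def feature_order(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        w = np.array([self.coefficients[k] for k in self.feature_order])
        return self.constant + X @ w

    def classify(self, X) -> np.ndarray:
        """True (hematuria) where the score is negative."""
        return self.score(X) < 0


def fit_discriminant(cohort: Cohort, partition: FactorPartition) -> DiscriminantFunction:
    """Two-class Fisher discriminant with the midpoint threshold rule.

    A singular pooled covariance is ridge-stabilised with an epsilon
    proportional to its trace (with a warning).
    """
    y = cohort.labels
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least two records per class")
    names = list(partition.feature_order)
    X = cohort.df[names].to_numpy(dtype=float)
    mu_pos = X[y].mean(axis=0)
    mu_neg = X[~y].mean(axis=0)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    S = (
        (X[y] - mu_pos).T @ (X[y] - mu_pos) + (X[~y] - mu_neg).T @ (X[~y] - mu_neg)
    ) / (n_pos + n_neg - 2)
    eps = 0.0
    if np.linalg.matrix_rank(S) < S.shape[0] or np.linalg.cond(S) > 1e12:
        eps = 1e-8 * np.trace(S) / S.shape[0]
        warnings.warn(
            f"singular pooled covariance; ridge-stabilising with eps={eps:.3e}",
            RuntimeWarning,
        )
        S = S + eps * np.eye(S.shape[0])
    # positive score toward the non-hematuria mean (published convention)
    w = np.linalg.solve(S, mu_neg - mu_pos)
    constant = -float(w @ (mu_pos + mu_neg) / 2.0)
    scores = constant + X @ w
    grand = scores.mean()
    ss_between = n_pos * (scores[y].mean() - grand) ** 2 + n_neg * (scores[~y].mean() - grand) ** 2
    ss_total = float(((scores - grand) ** 2).sum())
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    delta = float(np.sqrt((mu_neg - mu_pos) @ np.linalg.solve(S, mu_neg - mu_pos)))
    err_pct = float(100.0 * stats.norm.cdf(-delta / 2.0))
    return DiscriminantFunction(
        constant=constant,
        coefficients={n: float(c) for n, c in zip(names, w)},
        eta_squared=float(np.clip(eta2, 0.0, 1.0)),
        error_probability_pct=err_pct,
    )


@dataclass(frozen=True)
class PlaneLine:
    """A line a*fbg + b*fdp + c = 0 on the anchor plane."""

    a: float
    b: float
    c: float

    def fdp_at(self, fbg) -> np.ndarray | float:
        if abs(self.b) < 1e-12:
            raise ZeroDivisionError("line has no FDP dependence")
        out = -(self.c + self.a * np.asarray(fbg, dtype=float)) / self.b
        return float(out) if out.ndim == 0 else out

    def endpoints(self, fbg_lo: float = 0.0, fbg_hi: float = 170.0):
        return (
            (fbg_lo, self.fdp_at(fbg_lo)),
            (fbg_hi, self.fdp_at(fbg_hi)),
        )


def discriminant_plane_line(
    df: DiscriminantFunction, bundle: RegressionBundle
) -> PlaneLine:
    """Substitute the anchor regressions into the discriminant.

    Because all substituted regressions are linear in the anchors, the
    discriminant's zero set on the plane is exactly a straight line,
    invariant to rescaling the discriminant.  Raises when the net FDP
    coefficient degenerates to zero.
    """
    part = bundle.partition
    coef = df.coefficients
    a = coef.get(part.alpha, 0.0)
    b = coef.get(part.beta, 0.0)
    c = df.constant
    for name in part.auxiliaries:
        if name not in coef:
            raise ValueError(f"discriminant lacks a coefficient for {name}")
        reg = bundle.regressions[name]
        c += coef[name] * reg.intercept
        for pred, slope in zip(reg.predictors, reg.slopes):
            if pred == "alpha":
                a += coef[name] * slope
            else:
                b += coef[name] * slope
    if abs(b) < 1e-12:
        raise ZeroDivisionError("net FDP coefficient is zero; no plane line")
    return PlaneLine(a=float(a), b=float(b), c=float(c))


def fit_alpha_on_beta(cohort: Cohort) -> SimpleRegression:
    """OLS of fibrinogen on FDP with intercept, on the gated cohort."""
    x = cohort.df["fdp"].to_numpy(dtype=float)
    y = cohort.df["fbg"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("FDP is constant; regression undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return SimpleRegression(
        response="fbg",
        predictors=("beta",),
        params=tuple(float(v) for v in fit.params),
        bse=tuple(float(v) for v in fit.bse),
        pvalues=tuple(float(v) for v in fit.pvalues),
        aic=float(fit.aic),
        r_squared=float(np.clip(fit.rsquared, 0.0, 1.0)),
    )


@dataclass(frozen=True)
class FdpCriterion:
    """One-dimensional FDP threshold (mg/dL) for calling hematuria."""

    threshold: float
    method: str
    interval: tuple[float, float]
    tol: float

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.threshold <= hi):
            raise ValueError("threshold outside the search interval")


def fdp_criterion(
    plane: PlaneFunction,
    reg: SimpleRegression,
    interval: tuple[float, float] = (0.0, 150.0),
    tol: float = 1e-6,
    level: float = 0.5,
    method: str = "",
    n_scan: int = 1501,
) -> Optional[FdpCriterion]:
    """Smallest FDP in ``interval`` where the plane probability along the
    fibrinogen-on-FDP regression curve crosses ``level``.

    Evaluates q(FDP) = plane(reg(FDP), FDP) on a bracketing scan and
    bisects the first sign change.  Returns ``None`` (with a logged
    diagnostic) when q never crosses the level.
    """
    if reg.predictors != ("beta",):
        raise ValueError("fdp_criterion expects the fibrinogen-on-FDP regression")
    lo, hi = interval
    grid = np.linspace(lo, hi, n_scan)
    fbg = np.maximum(reg.predict(np.nan, grid), 0.0)
    q = plane(fbg, grid) - level

    def qf(beta_val: float) -> float:
        f = max(float(reg.predict(np.nan, beta_val)), 0.0)
        return float(plane(np.asarray(f), np.asarray(beta_val))) - level

    sign = np.sign(q)
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    exact = np.flatnonzero(sign == 0)
    if exact.size and (not idx.size or exact[0] <= idx[0]):
        root = float(grid[exact[0]])
    elif idx.size:
        i = idx[0]
        root = float(optimize.bisect(qf, grid[i], grid[i + 1], xtol=tol))
    else:
        logger.warning(
            "plane probability never crosses %.2f on FDP in [%g, %g] "
            "(range %.3f..%.3f); no 1-D criterion", level, lo, hi, q.min() + level, q.max() + level,
        )
        return None
    return FdpCriterion(threshold=root, method=method, interval=(lo, hi), tol=tol)
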