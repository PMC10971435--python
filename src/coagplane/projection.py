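"""Anchor regressions and projection of classifiers onto the anchor plane.

Each auxiliary factor is regressed (OLS with intercept) on its anchor(s):
P members on fibrinogen, Q members on FDP, R members on both.  Substituting
these fitted predictions for the auxiliaries reduces any classifier over
the full feature vector to a function p(fibrinogen, FDP) on the plane,
where its 0.5-level set is the clinical boundary.  Regressions are
evaluated over the whole plotting window, i.e. extrapolated outside the
fitted anchor range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort
from .partition import FactorPartition

__all__ = [
    "SimpleRegression",
    "RegressionBundle",
    "PlaneFunction",
    "fit_anchor_regressions",
    "reduce_to_plane",
]


@dataclass(frozen=True)
class SimpleRegression:
    """An OLS fit ``response = b0 + b1*pred1 (+ b2*pred2)`` with its report."""

    response: str
    predictors: tuple[str, ...]
    params: tuple[float, ...]  # (intercept, slope1[, slope2])
    bse: tuple[float, ...]
    pvalues: tuple[float, ...]
    aic: float
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.params) != len(self.predictors) + 1:
            raise ValueError("params must hold intercept plus one slope per predictor")
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise ValueError(f"R^2 out of range: {self.r_squared}")

    @property
    def intercept(self) -> float:
        return self.params[0]

    @property
    def slopes(self) -> tuple[float, ...]:
        return self.params[1:]

    def predict(self, alpha, beta):
        """Evaluate at anchor values; only the named predictors are used."""
        vals = {"alpha": np.asarray(alpha, dtype=float), "beta": np.asarray(beta, dtype=float)}
        out = np.full(np.broadcast(vals["alpha"], vals["beta"]).shape, self.intercept, dtype=float)
        for name, slope in zip(self.predictors, self.slopes):
            out = out + slope * vals[name]
        return out

    @classmethod
    def from_coefficients(
        cls, response: str, predictors: Sequence[str], params: Sequence[float],
        r_squared: float = 1.0,
    ) -> "SimpleRegression":
        k = len(params)
        return cls(
            response=response,
            predictors=tuple(predictors),
            params=tuple(float(p) for p in params),
            bse=(float("nan"),) * k,
            pvalues=(float("nan"),) * k,
            aic=float("nan"),
            r_squared=r_squared,
        )

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "params": list(self.params),
            "bse": list(self.bse),
            "pvalues": list(self.pvalues),
            "aic": self.aic,
            "r_squared": self.r_squared,
        }


@dataclass(frozen=True)
class RegressionBundle:
    """Fitted anchor regressions covering exactly the partition auxiliaries."""

    regressions: Mapping[str, SimpleRegression]
    partition: FactorPartition

    def __post_init__(self) -> None:
        covered = set(self.regressions)
        if covered != set(self.partition.auxiliaries):
            raise ValueError(
                f"bundle covers {sorted(covered)} but partition requires "
                f"{sorted(self.partition.auxiliaries)}"
            )
        for name in self.partition.P:
            if self.regressions[name].predictors != ("alpha",):
                raise ValueError(f"P member {name} must regress on alpha only")
        for name in self.partition.Q:
            if self.regressions[name].predictors != ("beta",):
                raise ValueError(f"Q member {name} must regress on beta only")
        for name in self.partition.R:
            if self.regressions[name].predictors != ("alpha", "beta"):
                raise ValueError(f"R member {name} must regress on alpha and beta")

    def expand(self, alpha, beta) -> np.ndarray:
        """Design matrix (n, n_features) in partition feature order, with
        auxiliaries replaced by their regression predictions."""
        alpha = np.asarray(alpha, dtype=float).ravel()
        beta = np.asarray(beta, dtype=float).ravel()
        if alpha.shape != beta.shape:
            raise ValueError("alpha and beta must have the same shape")
        cols = [alpha, beta]
        for name in self.partition.auxiliaries:
            cols.append(np.broadcast_to(self.regressions[name].predict(alpha, beta), alpha.shape))
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "partition": self.partition.to_dict(),
            "regressions": {k: v.to_dict() for k, v in self.regressions.items()},
        }


def _anchor_columns(cohort: Cohort, partition: FactorPartition, predictors: tuple[str, ...]):
    m = {"alpha": partition.alpha, "beta": partition.beta}
    return np.column_stack(
        [cohort.df[m[p]].to_numpy(dtype=float) for p in predictors]
    )


def fit_anchor_regressions(cohort: Cohort, partition: FactorPartition) -> RegressionBundle:
    """OLS with intercept for every auxiliary on its anchor(s).

    Reports estimates, heteroskedasticity-robust (HC3) standard errors,
    p-values, Gaussian AIC and R^2.  Raises on rank-deficient design
    (e.g. a constant anchor).
    """
    regs: dict[str, SimpleRegression] = {}
    for name in partition.auxiliaries:
        if name in partition.P:
            predictors: tuple[str, ...] = ("alpha",)
        elif name in partition.Q:
            predictors = ("beta",)
        else:
            predictors = ("alpha", "beta")
        X = _anchor_columns(cohort, partition, predictors)
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(f"rank-deficient design for {name}")
        y = cohort.df[name].to_numpy(dtype=float)
        # HC3 robust covariance: auxiliary residual spread scales with the
        # analyte's level, so classical SEs would understate slope
        # uncertainty on exactly the cohorts this package analyses
        with np.errstate(divide="ignore"):  # AIC is -inf on a perfect fit
            fit = sm.OLS(y, X).fit(cov_type="HC3")
        regs[name] = SimpleRegression(
            response=name,
            predictors=predictors,
            params=tuple(float(v) for v in fit.params),
            bse=tuple(float(v) for v in fit.bse),
            pvalues=tuple(float(v) for v in fit.pvalues),
            aic=float(fit.aic),
            r_squared=float(np.clip(fit.rsquared, 0.0, 1.0)),
        )
    return RegressionBundle(regressions=regs, partition=partition)


@dataclass
class PlaneFunction:
    """Hematuria probability as a function of the two anchors.

    Wraps a trained probabilistic classifier whose feature order equals the
    bundle's partition feature vector; evaluation substitutes regression
    predictions for the auxiliaries (vectorised over grids) and returns the
    probability of the positive (hematuria) class, always in [0, 1].
    """

    classifier: object
    bundle: RegressionBundle

    def __post_init__(self) -> None:
        order = getattr(self.classifier, "feature_order_", None)
        if order is not None and tuple(order) != tuple(self.bundle.partition.feature_order):
            raise ValueError(
                "classifier feature order does not match the regression bundle: "
                f"{tuple(order)} != {self.bundle.partition.feature_order}"
            )

    def __call__(self, alpha, beta) -> np.ndarray:
        alpha = np.asarray(alpha, dtype=float)
        beta = np.broadcast_to(np.asarray(beta, dtype=float), alpha.shape) if np.ndim(beta) == 0 else np.asarray(beta, dtype=float)
        alpha = np.broadcast_to(alpha, beta.shape) if alpha.shape != beta.shape else alpha
        shape = alpha.shape
        X = self.bundle.expand(alpha.ravel(), beta.ravel())
        proba = self.classifier.predict_proba(X)
        p = np.asarray(proba)[:, 1]
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("classifier returned probabilities outside [0, 1]")
        return np.clip(p, 0.0, 1.0).reshape(shape)


def reduce_to_plane(classifier, bundle: RegressionBundle) -> PlaneFunction:
    """Project a trained classifier onto the (fibrinogen, FDP) plane."""
    return PlaneFunction(classifier=classifier, bundle=bundle)
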