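"""Boundary learners on the fibrinogen/FDP plane.

Six probabilistic classifiers (logistic regression, random forest,
nearest neighbors, Gaussian naive Bayes, a small neural network and a
linear support vector machine) are trained on the gated cohort's feature
vector, projected onto the anchor plane, and their 0.5-probability level
sets extracted as boundary polylines.  The published SVM plane rule
``fdp - fbg/3 - 60 > 0  =>  hematuria`` is exposed as a fixed reference
criterion.

Hyperparameters follow documented defaults (the reference platform's
automatic settings are not reproducible): unpenalised logistic regression
and the linear SVM use class weights inverse to class frequency (3 vs 20
positives would otherwise collapse to the majority class); SVM, nearest
neighbors and the neural network see z-scored features; trees and naive
Bayes use the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort
from .partition import FactorPartition
from .projection import PlaneFunction
from .reference import SVM_RULE

__all__ = [
    "METHODS",
    "PlaneBoundaryClassifier",
    "train_classifier",
    "GridSpec",
    "ProbabilityField",
    "probability_grid",
    "BoundaryGeometry",
    "extract_boundary",
    "svm_criterion",
    "svm_boundary_fdp",
]

METHODS = (
    "logistic",
    "random_forest",
    "nearest_neighbors",
    "naive_bayes",
    "neural_network",
    "svm",
)


def _base_estimator(method: str, seed: int):
    if method == "logistic":
        # C=inf: unpenalised maximum likelihood
        return LogisticRegression(
            C=np.inf, class_weight="balanced", max_iter=5000, solver="lbfgs"
        )
    if method == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if method == "nearest_neighbors":
        return make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=3, weights="distance")
        )
    if method == "naive_bayes":
        return GaussianNB()
    if method == "neural_network":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(8,),
                activation="logistic",
                solver="lbfgs",
                max_iter=4000,
                random_state=seed,
            ),
        )
    if method == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(
                kernel="linear",
                C=1.0,
                probability=True,
                class_weight="balanced",
                random_state=seed,
            ),
        )
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


class PlaneBoundaryClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn classifier wrapper around the six boundary learners.

    Parameters
    ----------
    method : one of :data:`METHODS`
    seed : int, seeds every stochastic component (forest, network, Platt
        scaling) so refits are reproducible.

    Attributes
    ----------
    estimator_ : the fitted underlying pipeline/estimator
    classes_ : ndarray [False, True]
    feature_order_ : tuple of str, when fitted from a DataFrame
    """

    def __init__(self, method: str = "svm", seed: int = 0):
        self.method = method
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y, dtype=bool)
        if y.all() or not y.any():
            raise ValueError("training labels contain a single class")
        names = tuple(X.columns) if hasattr(X, "columns") else None
        X = np.asarray(X, dtype=float)
        est = _base_estimator(self.method, self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(X, y)
        self.estimator_ = est
        self.classes_ = np.array([False, True])
        self.feature_order_ = names
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        proba = self.estimator_.predict_proba(X)
        # underlying classes_ is sorted [False, True]; keep that order
        s = proba.sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("class probabilities do not sum to 1")
        return proba

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1] > 0.5

    def decision_plane_coefficients(self) -> Optional[tuple[np.ndarray, float]]:
        """(weights, intercept) in raw feature space for linear methods."""
        check_is_fitted(self, "estimator_")
        est = self.estimator_
        if self.method == "svm":
            scaler, svc = est.named_steps["standardscaler"], est.named_steps["svc"]
            w = svc.coef_[0] / scaler.scale_
            b = svc.intercept_[0] - np.sum(svc.coef_[0] * scaler.mean_ / scaler.scale_)
            return w, float(b)
        if self.method == "logistic":
            return est.coef_[0].copy(), float(est.intercept_[0])
        return None


def train_classifier(
    cohort: Cohort, partition: FactorPartition, method: str, seed: int = 0
) -> PlaneBoundaryClassifier:
    """Fit one boundary learner on the cohort's partition feature vector."""
    X = cohort.df[list(partition.feature_order)]
    clf = PlaneBoundaryClassifier(method=method, seed=seed)
    return clf.fit(X, cohort.labels)


@dataclass(frozen=True)
class GridSpec:
    """Inclusive uniform grid over the anchor plane (mg/dL)."""

    alpha_min: float = 0.0
    alpha_max: float = 170.0
    alpha_step: float = 1.0
    beta_min: float = 0.0
    beta_max: float = 150.0
    beta_step: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_step <= 0 or self.beta_step <= 0:
            raise ValueError("grid steps must be positive")

    @property
    def alpha(self) -> np.ndarray:
        n = int(round((self.alpha_max - self.alpha_min) / self.alpha_step)) + 1
        return self.alpha_min + self.alpha_step * np.arange(n)

    @property
    def beta(self) -> np.ndarray:
        n = int(round((self.beta_max - self.beta_min) / self.beta_step)) + 1
        return self.beta_min + self.beta_step * np.arange(n)


@dataclass(frozen=True)
class ProbabilityField:
    """p(hematuria) sampled on a grid.

    ``values[i, j]`` is the probability at ``(alpha[i], beta[j])``:
    fibrinogen varies along rows (ascending), FDP along columns
    (ascending).
    """

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        expect = (self.grid.alpha.size, self.grid.beta.size)
        if self.values.shape != expect:
            raise ValueError(f"field shape {self.values.shape} != grid shape {expect}")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("probabilities outside [0, 1]")


def probability_grid(plane: PlaneFunction | callable, grid: GridSpec = GridSpec()) -> ProbabilityField:
    """Evaluate a plane function element-wise over the grid."""
    A, B = np.meshgrid(grid.alpha, grid.beta, indexing="ij")
    vals = np.asarray(plane(A, B), dtype=float)
    return ProbabilityField(grid=grid, values=np.clip(vals, 0.0, 1.0))


@dataclass(frozen=True)
class CrudeRegion:
    """Tightest axis-aligned half-plane description of the hematuria region."""

    fdp_gt: Optional[float]
    fbg_lt: Optional[float]
    text: str


@dataclass(frozen=True)
class BoundaryGeometry:
    """Level-set polylines plus crude region and a fitted linear form."""

    level: float
    polylines: tuple[np.ndarray, ...]  # each (n, 2) array of (fbg, fdp) vertices
    crude_region: CrudeRegion
    linear_form: Optional[tuple[float, float, float]]  # a*fbg + b*fdp + c = 0
    linear_rms: Optional[float]
    grid: GridSpec

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "polylines": [p.tolist() for p in self.polylines],
            "crude_region": {
                "fdp_gt": self.crude_region.fdp_gt,
                "fbg_lt": self.crude_region.fbg_lt,
                "text": self.crude_region.text,
            },
            "linear_form": list(self.linear_form) if self.linear_form else None,
            "linear_rms": self.linear_rms,
        }


def _crude_region(field: ProbabilityField, level: float) -> CrudeRegion:
    g = field.grid
    mask = field.values > level
    if not mask.any():
        return CrudeRegion(fdp_gt=None, fbg_lt=None, text="empty")
    ai, bi = np.nonzero(mask)
    fdp_min = float(g.beta[bi.min()])
    fbg_max = float(g.alpha[ai.max()])
    parts = []
    fdp_gt: Optional[float] = None
    fbg_lt: Optional[float] = None
    if fdp_min > g.beta_min + 0.5 * g.beta_step:
        fdp_gt = fdp_min
        parts.append(f"FDP > {fdp_min:g} mg/dL")
    if fbg_max < g.alpha_max - 0.5 * g.alpha_step:
        fbg_lt = fbg_max
        parts.append(f"fibrinogen < {fbg_max:g} mg/dL")
    return CrudeRegion(fdp_gt=fdp_gt, fbg_lt=fbg_lt, text=" and ".join(parts) or "entire window")


def _fit_linear_form(
    polylines: tuple[np.ndarray, ...], field: ProbabilityField, level: float
):
    """Total-least-squares line through all boundary vertices, oriented so
    the positive side is the super-level (hematuria) side."""
    if not polylines:
        return None, None
    pts = np.vstack(polylines)
    if len(pts) < 2:
        return None, None
    centre = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centre, full_matrices=False)
    normal = vt[-1]  # direction of least variance
    a, b = float(normal[0]), float(normal[1])
    c = -float(normal @ centre)
    resid = (pts @ normal + c)
    rms = float(np.sqrt(np.mean(resid**2)))
    # orient: probe slightly off-centre along the normal
    g = field.grid
    step = 2.0 * max(g.alpha_step, g.beta_step)
    probe = centre + step * normal
    ai = int(np.clip(round((probe[0] - g.alpha_min) / g.alpha_step), 0, g.alpha.size - 1))
    bi = int(np.clip(round((probe[1] - g.beta_min) / g.beta_step), 0, g.beta.size - 1))
    if field.values[ai, bi] < level:
        a, b, c = -a, -b, -c
    if abs(b) > 1e-9:
        a, b, c = a / b, 1.0, c / b
    return (a, b, c), rms


def extract_boundary(field: ProbabilityField, level: float = 0.5) -> BoundaryGeometry:
    """Marching-squares level set of the probability field.

    Vertices are linearly interpolated on grid edges (so the interpolated
    probability along a crossed edge passes through ``level``) and mapped
    to (fbg, fdp) coordinates.  Also reports the crude axis-aligned region
    of the super-level set and a fitted linear form of the boundary.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie strictly inside (0, 1)")
    g = field.grid
    contours = measure.find_contours(field.values, level)
    polylines = []
    for c in contours:
        fbg = g.alpha_min + c[:, 0] * g.alpha_step
        fdp = g.beta_min + c[:, 1] * g.beta_step
        polylines.append(np.column_stack([fbg, fdp]))
    polylines = tuple(polylines)
    crude = _crude_region(field, level)
    linear_form, rms = _fit_linear_form(polylines, field, level)
    return BoundaryGeometry(
        level=level,
        polylines=polylines,
        crude_region=crude,
        linear_form=linear_form,
        linear_rms=rms,
        grid=g,
    )


def svm_criterion(fbg, fdp):
    """The published SVM plane rule: value = fdp - fbg/3 - 60 (mg/dL).

    Positive value indicates hematuria; labels are returned alongside the
    signed value.  Scalar in, scalar out; arrays broadcast.
    """
    fbg = np.asarray(fbg, dtype=float)
    fdp = np.asarray(fdp, dtype=float)
    if np.any(fbg < 0) or np.any(fdp < 0):
        raise ValueError("analyte values must be non-negative")
    a, b, c = SVM_RULE
    value = a * fbg + b * fdp + c
    label = value > 0
    if value.ndim == 0:
        return float(value), bool(label)
    return value, label


def svm_boundary_fdp(fbg) -> np.ndarray | float:
    """FDP coordinate of the published rule's zero level at given fibrinogen."""
    from scipy.optimize import brentq

    def solve(f):
        return brentq(lambda d: svm_criterion(f, d)[0], 0.0, 1000.0, xtol=1e-12)

    fbg = np.asarray(fbg, dtype=float)
    if fbg.ndim == 0:
        return float(solve(float(fbg)))
    return np.array([solve(float(f)) for f in fbg])
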