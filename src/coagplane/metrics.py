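"""Classification performance metrics for the boundary report tables.

Implements the reference report columns from first principles: accuracy
with its binomial standard error, rank-based AUC (probability that a
random positive outscores a random negative, ties counting one half),
class mean class entropy (per-class average negative log-probability of
the true class, averaged across classes, natural log), Cohen's kappa,
F1, PPV, sensitivity and specificity.  Evaluation is resubstitution by
default — the scheme consistent with the reference confusion matrices at
n=23 — with leave-one-out available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import LeaveOneOut

from .cohort import Cohort
from .partition import FactorPartition

__all__ = [
    "ConfusionMatrix",
    "confusion_metrics",
    "auc",
    "class_mean_class_entropy",
    "evaluate_all",
    "REPORT_COLUMNS",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "accuracy", "accuracy_sd", "auc", "cmce", "kappa",
    "f1", "ppv", "sensitivity", "specificity",
)

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must hold at least one record")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int((t & p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
            tn=int((~t & ~p).sum()),
        )


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Rates derived from a confusion matrix.

    Metrics with zero denominators are reported as ``None``.  The accuracy
    SD is the binomial standard error sqrt(acc*(1-acc)/N); kappa uses the
    marginal-product chance agreement.
    """
    n = cm.total
    acc = (cm.tp + cm.tn) / n
    sens = _safe_div(cm.tp, cm.tp + cm.fn)
    spec = _safe_div(cm.tn, cm.tn + cm.fp)
    ppv = _safe_div(cm.tp, cm.tp + cm.fp)
    f1 = _safe_div(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    pe = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / n**2
    kappa = (acc - pe) / (1 - pe) if pe < 1 else 1.0 if acc == 1.0 else 0.0
    return {
        "accuracy": acc,
        "accuracy_sd": float(np.sqrt(acc * (1 - acc) / n)),
        "kappa": kappa,
        "f1": f1,
        "ppv": ppv,
        "sensitivity": sens,
        "specificity": spec,
    }


def auc(labels, scores) -> float:
    """Rank (Mann-Whitney) AUC: P(score_pos > score_neg) with ties = 1/2."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # midranks handle ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def class_mean_class_entropy(labels, proba) -> float:
    """Per-class mean of -ln p(true class), averaged across the two classes.

    ``proba`` holds rows of class probabilities ordered [negative,
    positive].  Zero probabilities on a realised class are clamped at
    1e-12 with a warning.
    """
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(proba, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] != y.size:
        raise ValueError("proba must be (n, 2) aligned with labels")
    p_true = np.where(y, p[:, 1], p[:, 0])
    if np.any(p_true <= 0):
        logger.warning("zero probability assigned to a realised class; clamping at 1e-12")
        p_true = np.maximum(p_true, _PROB_FLOOR)
    terms = -np.log(p_true)
    vals = []
    for cls in (True, False):
        if (y == cls).any():
            vals.append(terms[y == cls].mean())
    return float(np.mean(vals))


def _predictions(clf, X, y, scheme: str, seed: int = 0):
    if scheme == "resubstitution":
        return np.asarray(clf.predict_proba(X))
    if scheme == "leave-one-out":
        from sklearn.base import clone

        proba = np.empty((len(y), 2))
        for train, test in LeaveOneOut().split(X):
            if len(set(y[train])) < 2:
                proba[test] = [0.5, 0.5]
                continue
            m = clone(clf).fit(X[train], y[train])
            proba[test] = m.predict_proba(X[test])
        return proba
    raise ValueError(f"unknown evaluation scheme {scheme!r}")


def evaluate_all(
    classifiers: Mapping[str, object],
    cohort: Cohort,
    partition: FactorPartition,
    scheme: str = "resubstitution",
) -> pd.DataFrame:
    """One metrics row per trained classifier, in the report column order."""
    y = cohort.labels
    X = cohort.df[list(partition.feature_order)].to_numpy(dtype=float)
    rows = {}
    for tag, clf in classifiers.items():
        proba = _predictions(clf, X, y, scheme)
        pred = proba[:, 1] > 0.5
        cm = ConfusionMatrix.from_labels(y, pred)
        row = confusion_metrics(cm)
        row["auc"] = auc(y, proba[:, 1])
        row["cmce"] = class_mean_class_entropy(y, proba)
        rows[tag] = [row[c] for c in REPORT_COLUMNS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(REPORT_COLUMNS))
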