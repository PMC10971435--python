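"""Multicollinearity-avoiding factor partition around the two anchors.

The two rapidly available analytes — fibrinogen (anchor alpha) and FDP
(anchor beta) — span the plane on which the clinical boundary is drawn.
Every other factor is assessed by its *contribution rate* to each anchor,
the squared Pearson correlation r^2 (the coefficient of determination of
the simple linear regression).  Factors with contribution rate > 0.49
(|r| > 0.7) to an anchor form the related sets A (to fibrinogen) and
B (to FDP), which are split into

* P = A \\ B  (related to fibrinogen only),
* Q = B \\ A  (related to FDP only),
* R = A & B  (related to both),

and each of P, Q, R is pruned greedily until every within-set pair has
contribution rate < CR = 0.64 (|r| < 0.8), removing multicollinear
duplicates such as PT-INR (a transform of PT-sec) and PIC (tied to
D-dimer).  The ordered feature vector is (alpha, beta, P..., Q..., R...),
each block sorted by pruning priority (ascending univariate t-test
p-value, ties alphabetical).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, FACTOR_COLUMNS
from .screening import t_pvalue_ranking

__all__ = [
    "RELATE_THRESHOLD",
    "COLLINEARITY_CEILING",
    "FactorPartition",
    "contribution_rate",
    "build_related_sets",
    "partition_factors",
    "prune_collinear",
    "feature_vector_spec",
    "derive_partition",
    "FactorPartitioner",
]

RELATE_THRESHOLD = 0.49
COLLINEARITY_CEILING = 0.64


def contribution_rate(x, y) -> float:
    """Squared Pearson correlation between two equal-length vectors.

    Symmetric, invariant to affine rescaling of either argument, and equal
    to the R^2 of the simple linear regression of either variable on the
    other.  Inputs must be non-constant with length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("contribution rate is undefined for constant input")
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(r * r, 0.0, 1.0))


@dataclass(frozen=True)
class FactorPartition:
    """Anchor names plus the related sets and the ordered feature vector."""

    alpha: str
    beta: str
    A: frozenset[str]
    B: frozenset[str]
    P: tuple[str, ...]
    Q: tuple[str, ...]
    R: tuple[str, ...]
    feature_order: tuple[str, ...]
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"relate": RELATE_THRESHOLD, "CR": COLLINEARITY_CEILING}
    )

    def __post_init__(self) -> None:
        p, q, r = set(self.P), set(self.Q), set(self.R)
        if p & q or p & r or q & r:
            raise ValueError("P, Q, R must be pairwise disjoint")
        if not p <= (self.A - self.B) or not q <= (self.B - self.A) or not r <= (self.A & self.B):
            raise ValueError("P/Q/R must come from A\\B, B\\A, A&B respectively")
        if {self.alpha, self.beta} & (p | q | r):
            raise ValueError("anchors cannot appear among the auxiliary sets")
        expect = (self.alpha, self.beta) + self.P + self.Q + self.R
        if self.feature_order != expect:
            raise ValueError("feature_order must be (alpha, beta, P..., Q..., R...)")

    @property
    def auxiliaries(self) -> tuple[str, ...]:
        return self.P + self.Q + self.R

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "A": sorted(self.A),
            "B": sorted(self.B),
            "P": list(self.P),
            "Q": list(self.Q),
            "R": list(self.R),
            "feature_order": list(self.feature_order),
            "thresholds": dict(self.thresholds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorPartition":
        return cls(
            alpha=d["alpha"],
            beta=d["beta"],
            A=frozenset(d["A"]),
            B=frozenset(d["B"]),
            P=tuple(d["P"]),
            Q=tuple(d["Q"]),
            R=tuple(d["R"]),
            feature_order=tuple(d["feature_order"]),
            thresholds=dict(d.get("thresholds", {})),
        )


def build_related_sets(
    cohort: Cohort,
    alpha: str = "fbg",
    beta: str = "fdp",
    relate_threshold: float = RELATE_THRESHOLD,
    require_significant: bool = False,
    significance: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Sets A and B of factors whose contribution rate to an anchor exceeds
    the relatedness threshold (anchors excluded from both sets).

    With ``require_significant`` membership additionally requires a
    univariate t-test p-value below ``significance``.
    """
    if len(cohort) < 4:
        raise ValueError("need at least four records to assess relatedness")
    pvals = t_pvalue_ranking(cohort) if require_significant else None
    xa = cohort.df[alpha].to_numpy(dtype=float)
    xb = cohort.df[beta].to_numpy(dtype=float)
    A: set[str] = set()
    B: set[str] = set()
    for f in FACTOR_COLUMNS:
        if f in (alpha, beta):
            continue
        v = cohort.df[f].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            continue  # constant factor carries no relation
        if pvals is not None and pvals.get(f, 1.0) >= significance:
            continue
        if contribution_rate(v, xa) > relate_threshold:
            A.add(f)
        if contribution_rate(v, xb) > relate_threshold:
            B.add(f)
    return A, B


def partition_factors(A: Iterable[str], B: Iterable[str]) -> tuple[set[str], set[str], set[str]]:
    """Raw partition of A | B into (A\\B, B\\A, A&B)."""
    A, B = set(A), set(B)
    return A - B, B - A, A & B


def prune_collinear(
    members: Iterable[str],
    cohort: Cohort,
    ceiling: float = COLLINEARITY_CEILING,
    priority: Optional[Mapping[str, float]] = None,
) -> tuple[str, ...]:
    """Greedy within-set pruning until every pair has contribution rate < CR.

    ``priority`` maps names to sort keys (smaller = keep first; default
    alphabetical).  Whenever a pair violates the ceiling, the worst offending
    pair is found and its lower-priority member dropped.  Returns the
    surviving members in priority order.
    """
    def key(name: str):
        if priority is None:
            return (0.0, name)
        return (priority.get(name, float("inf")), name)

    alive = sorted(set(members), key=key)
    data = {f: cohort.df[f].to_numpy(dtype=float) for f in alive}
    while True:
        worst, worst_cr = None, ceiling
        for a, b in itertools.combinations(alive, 2):
            cr = contribution_rate(data[a], data[b])
            if cr >= worst_cr:
                worst, worst_cr = (a, b), cr
        if worst is None:
            return tuple(alive)
        drop = max(worst, key=key)
        alive.remove(drop)


def feature_vector_spec(partition: FactorPartition) -> tuple[str, ...]:
    """Ordered classifier feature names: anchors, then P, Q, R blocks."""
    return partition.feature_order


def derive_partition(
    cohort: Cohort,
    alpha: str = "fbg",
    beta: str = "fdp",
    relate_threshold: float = RELATE_THRESHOLD,
    ceiling: float = COLLINEARITY_CEILING,
    require_significant: bool = False,
) -> FactorPartition:
    """Full partition pipeline: related sets -> P/Q/R -> pruning -> ordering.

    Pruning priority is the ascending univariate t-test p-value on the
    cohort, ties broken alphabetically.
    """
    A, B = build_related_sets(
        cohort, alpha=alpha, beta=beta,
        relate_threshold=relate_threshold, require_significant=require_significant,
    )
    p_raw, q_raw, r_raw = partition_factors(A, B)
    # p-values are rounded to 10 significant digits so that exactly collinear
    # factors (identical tests up to float noise) tie and fall to the
    # alphabetical tie-break
    priority = {
        f: float(f"{p:.10g}") for f, p in t_pvalue_ranking(cohort).items()
    }
    P = prune_collinear(p_raw, cohort, ceiling=ceiling, priority=priority)
    Q = prune_collinear(q_raw, cohort, ceiling=ceiling, priority=priority)
    R = prune_collinear(r_raw, cohort, ceiling=ceiling, priority=priority)
    part = FactorPartition(
        alpha=alpha,
        beta=beta,
        A=frozenset(A),
        B=frozenset(B),
        P=P,
        Q=Q,
        R=R,
        feature_order=(alpha, beta) + P + Q + R,
        thresholds={"relate": relate_threshold, "CR": ceiling},
    )
    _assert_pruned(part, cohort)
    return part


def _assert_pruned(part: FactorPartition, cohort: Cohort) -> None:
    for block in (part.P, part.Q, part.R):
        for a, b in itertools.combinations(block, 2):
            cr = contribution_rate(
                cohort.df[a].to_numpy(float), cohort.df[b].to_numpy(float)
            )
            if cr >= part.thresholds["CR"]:
                raise AssertionError(f"pruning left collinear pair ({a}, {b}): cr={cr:.3f}")


def reference_partition() -> FactorPartition:
    """The canonical partition of the reference study.

    Hgb/fbg, PT-sec and PT-INR relate to fibrinogen; D-dimer and PIC to
    FDP; pruning leaves the five-factor vector
    (fbg, fdp, hgb_fbg, pt_sec, dd) of the published discriminant.  Useful
    for parameter-recovery workflows where the structure is known a priori.
    """
    return FactorPartition(
        alpha="fbg",
        beta="fdp",
        A=frozenset({"hgb_fbg", "pt_sec", "pt_inr"}),
        B=frozenset({"dd", "pic"}),
        P=("hgb_fbg", "pt_sec"),
        Q=("dd",),
        R=(),
        feature_order=("fbg", "fdp", "hgb_fbg", "pt_sec", "dd"),
    )


class FactorPartitioner(TransformerMixin, BaseEstimator):
    """scikit-learn transformer wrapping :func:`derive_partition`.

    ``fit`` expects ``X`` as a DataFrame holding the 15 factor columns and
    ``y`` as the binary hematuria labels (needed for the pruning priority);
    ``transform`` reorders/selects columns to the fitted feature vector.

    Attributes
    ----------
    partition_ : FactorPartition
    feature_names_out_ : tuple of str
    """

    def __init__(
        self,
        alpha: str = "fbg",
        beta: str = "fdp",
        relate_threshold: float = RELATE_THRESHOLD,
        ceiling: float = COLLINEARITY_CEILING,
        require_significant: bool = False,
    ):
        self.alpha = alpha
        self.beta = beta
        self.relate_threshold = relate_threshold
        self.ceiling = ceiling
        self.require_significant = require_significant

    def fit(self, X, y):
        import pandas as pd

        df = pd.DataFrame(X).copy()
        df["hematuria"] = np.asarray(y, dtype=bool)
        cohort = Cohort(df=df, provenance="FactorPartitioner.fit")
        self.partition_ = derive_partition(
            cohort,
            alpha=self.alpha,
            beta=self.beta,
            relate_threshold=self.relate_threshold,
            ceiling=self.ceiling,
            require_significant=self.require_significant,
        )
        self.feature_names_out_ = self.partition_.feature_order
        return self

    def transform(self, X):
        check_is_fitted(self, "partition_")
        import pandas as pd

        return pd.DataFrame(X)[list(self.feature_names_out_)]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "partition_")
        return np.asarray(self.feature_names_out_, dtype=object)
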