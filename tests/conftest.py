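"""Shared fixtures: the default synthetic study cohort and trained models.

Expensive artifacts (default cohort, partition, regressions, trained
classifiers, probability fields, the 300-seed coverage sweep) are
session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coagplane.boundaries import (
    METHODS,
    GridSpec,
    extract_boundary,
    probability_grid,
    train_classifier,
)
from coagplane.cohort import FACTOR_COLUMNS, Cohort, filter_coagulation_failure
from coagplane.partition import derive_partition, reference_partition
from coagplane.projection import fit_anchor_regressions, reduce_to_plane
from coagplane.simulate import GeneratorConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", category=FutureWarning)


def make_cohort(columns: dict, labels, seed: int = 0) -> Cohort:
    """Build a cohort from a few explicit columns, filling the remaining
    factors with benign positive noise (test scaffolding only)."""
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    # spawn a stream distinct from any plain default_rng(seed) a caller may
    # have used to build its explicit columns
    rng = np.random.default_rng([seed, 9973])
    data = {}
    for c in FACTOR_COLUMNS:
        if c in columns:
            data[c] = np.asarray(columns[c], dtype=float)
        else:
            data[c] = rng.uniform(10.0, 20.0, size=n)
    data["hematuria"] = labels
    df = pd.DataFrame(data)
    return Cohort(df=df, provenance="test-fixture")


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def gated(default_cohort) -> Cohort:
    return filter_coagulation_failure(default_cohort)


@pytest.fixture(scope="session")
def canonical_partition(gated):
    return derive_partition(gated)


@pytest.fixture(scope="session")
def bundle(gated, canonical_partition):
    return fit_anchor_regressions(gated, canonical_partition)


@pytest.fixture(scope="session")
def trained(gated, canonical_partition):
    """All six classifiers trained on the default gated cohort (seed 0)."""
    return {
        m: train_classifier(gated, canonical_partition, m, seed=0) for m in METHODS
    }


@pytest.fixture(scope="session")
def planes(trained, bundle):
    return {m: reduce_to_plane(clf, bundle) for m, clf in trained.items()}


@pytest.fixture(scope="session")
def fields(planes):
    return {m: probability_grid(p, GridSpec()) for m, p in planes.items()}


@pytest.fixture(scope="session")
def geometries(fields):
    return {m: extract_boundary(f, level=0.5) for m, f in fields.items()}


@pytest.fixture(scope="session")
def zero_noise_gated() -> Cohort:
    cohort = generate_cohort(GeneratorConfig(seed=7, noise_scale=0.0))
    return filter_coagulation_failure(cohort)


@pytest.fixture(scope="session")
def coverage_counts():
    """2-SE coverage of the anchor-regression estimates over 300 seeded
    noisy cohorts scaled to ~200 gated records (26 + 174)."""
    ref = reference_partition()
    hits = {"hgb_fbg_intercept": 0, "dd_slope": 0}
    n_seeds = 300
    for s in range(n_seeds):
        cohort = generate_cohort(
            GeneratorConfig(n_hematuria=26, n_non=174, n_above_gate=0, seed=s)
        )
        b = fit_anchor_regressions(filter_coagulation_failure(cohort), ref)
        r = b.regressions["hgb_fbg"]
        hits["hgb_fbg_intercept"] += abs(r.params[0] - 174.41) <= 2 * r.bse[0]
        r = b.regressions["dd"]
        hits["dd_slope"] += abs(r.params[1] - 3.4946) <= 2 * r.bse[1]
    return {k: v / n_seeds for k, v in hits.items()}
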