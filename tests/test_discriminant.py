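"""Fisher discriminant, its plane boundary line, the fibrinogen-on-FDP
regression and the one-dimensional FDP criteria."""

import numpy as np
import pytest
from scipy.stats import norm

from coagplane.discriminant import (
    DiscriminantFunction,
    discriminant_plane_line,
    fdp_criterion,
    fit_alpha_on_beta,
    fit_discriminant,
)
from coagplane.partition import FactorPartition, reference_partition
from coagplane.projection import (
    RegressionBundle,
    SimpleRegression,
    fit_anchor_regressions,
    reduce_to_plane,
)
from coagplane.reference import ALPHA_ON_BETA, DISCRIMINANT

from conftest import make_cohort


def _printed_discriminant():
    return DiscriminantFunction(
        constant=DISCRIMINANT["constant"],
        coefficients=dict(DISCRIMINANT["coefficients"]),
        eta_squared=DISCRIMINANT["eta_squared"],
        error_probability_pct=DISCRIMINANT["error_probability_pct"],
    )


def _printed_bundle():
    regs = {
        "hgb_fbg": SimpleRegression.from_coefficients("hgb_fbg", ("alpha",), (174.41, -0.898)),
        "pt_sec": SimpleRegression.from_coefficients("pt_sec", ("alpha",), (19.681, -0.048)),
        "dd": SimpleRegression.from_coefficients("dd", ("beta",), (-9.535, 3.4946)),
    }
    return RegressionBundle(regressions=regs, partition=reference_partition())


class TestFitDiscriminant:
    def test_separated_gaussian_clouds_have_tiny_error_probability(self):
        """Closed-form oracle: two spherical Gaussians at Mahalanobis
        distance d have Bayes error Phi(-d/2)."""
        rng = np.random.default_rng(0)
        n = 120
        d = 6.0
        names = ("fbg", "fdp", "hgb_fbg", "pt_sec", "dd")
        pos = rng.normal(0, 1, size=(n, 5)) + 50.0
        neg = rng.normal(0, 1, size=(n, 5)) + 50.0
        pos[:, 0] += d  # separation along one axis
        cols = {k: np.concatenate([pos[:, i], neg[:, i]]) for i, k in enumerate(names)}
        c = make_cohort(cols, [True] * n + [False] * n)
        df = fit_discriminant(c, reference_partition())
        assert df.error_probability_pct < 1.0
        # invert the normal-theory error back to a Mahalanobis distance and
        # compare with the true separation (tail probabilities amplify the
        # in-sample distance inflation, distances do not)
        d_est = -2.0 * norm.ppf(df.error_probability_pct / 100.0)
        assert d_est == pytest.approx(d, rel=0.10)

    def test_identical_class_distributions_have_near_zero_eta_squared(self):
        rng = np.random.default_rng(1)
        n = 400
        names = ("fbg", "fdp", "hgb_fbg", "pt_sec", "dd")
        cols = {k: rng.normal(50, 5, size=n) for k in names}
        c = make_cohort(cols, rng.random(n) < 0.5)
        df = fit_discriminant(c, reference_partition())
        assert df.eta_squared < 0.1

    def test_fdp_coefficient_sign_matches_the_published_function(self, gated, canonical_partition):
        """Positive score = non-hematuria, so the FDP coefficient is
        negative: higher FDP pushes toward the hematuria side."""
        df = fit_discriminant(gated, canonical_partition)
        assert df.coefficients["fdp"] < 0
        scores = df.score(gated.df[list(canonical_partition.feature_order)].to_numpy(float))
        assert scores[gated.labels].mean() < scores[~gated.labels].mean()

    def test_eta_squared_equals_the_correlation_ratio_form(self, gated, canonical_partition):
        df = fit_discriminant(gated, canonical_partition)
        X = gated.df[list(canonical_partition.feature_order)].to_numpy(float)
        scores = df.score(X)
        y = gated.labels.astype(float)
        r2 = np.corrcoef(scores, y)[0, 1] ** 2  # two-group eta^2 == r^2
        assert df.eta_squared == pytest.approx(r2, abs=1e-10)

    def test_too_few_records_per_class_rejected(self):
        c = make_cohort({}, [True] + [False] * 9)
        with pytest.raises(ValueError):
            fit_discriminant(c, reference_partition())


class TestPlaneLine:
    def test_printed_substitution_hits_the_published_endpoints(self):
        line = discriminant_plane_line(_printed_discriminant(), _printed_bundle())
        (x0, y0), (x1, y1) = line.endpoints(0.0, 170.0)
        assert y0 == pytest.approx(50.0, abs=5.0)
        assert y1 == pytest.approx(68.0, abs=5.0)

    def test_fdp_only_discriminant_gives_a_horizontal_line(self):
        df = DiscriminantFunction(
            constant=40.0,
            coefficients={"fbg": 0.0, "fdp": -0.5, "hgb_fbg": 0.0, "pt_sec": 0.0, "dd": 0.0},
            eta_squared=0.5,
            error_probability_pct=1.0,
        )
        line = discriminant_plane_line(df, _printed_bundle())
        assert line.fdp_at(0.0) == pytest.approx(line.fdp_at(170.0))

    def test_zero_set_is_invariant_to_rescaling(self):
        base = _printed_discriminant()
        doubled = DiscriminantFunction(
            constant=2 * base.constant,
            coefficients={k: 2 * v for k, v in base.coefficients.items()},
            eta_squared=base.eta_squared,
            error_probability_pct=base.error_probability_pct,
        )
        bundle = _printed_bundle()
        l1 = discriminant_plane_line(base, bundle)
        l2 = discriminant_plane_line(doubled, bundle)
        for x in (0.0, 85.0, 170.0):
            assert l1.fdp_at(x) == pytest.approx(l2.fdp_at(x), abs=1e-9)

    def test_degenerate_fdp_coefficient_raises(self):
        df = DiscriminantFunction(
            constant=1.0,
            coefficients={"fbg": -1.0, "fdp": 0.0, "hgb_fbg": 0.0, "pt_sec": 0.0, "dd": 0.0},
            eta_squared=0.5,
            error_probability_pct=1.0,
        )
        with pytest.raises(ZeroDivisionError):
            discriminant_plane_line(df, _printed_bundle())


class TestAlphaOnBeta:
    def test_zero_noise_line_recovered_exactly(self):
        fdp = np.linspace(5, 96, 23)
        fbg = ALPHA_ON_BETA.intercept + ALPHA_ON_BETA.slope * fdp
        c = make_cohort({"fdp": fdp, "fbg": fbg}, [True] * 3 + [False] * 20)
        reg = fit_alpha_on_beta(c)
        assert reg.params[0] == pytest.approx(132.905, abs=1e-9)
        assert reg.params[1] == pytest.approx(-0.6613, abs=1e-12)

    def test_two_se_coverage_on_noisy_replicates(self):
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            fdp = rng.uniform(3, 110, 200)
            fbg = 132.905 - 0.6613 * fdp + rng.normal(0, 15, 200)
            c = make_cohort({"fdp": fdp, "fbg": fbg}, [True] * 30 + [False] * 170)
            reg = fit_alpha_on_beta(c)
            hits += abs(reg.params[1] + 0.6613) <= 2 * reg.bse[1]
        assert hits / n_rep >= 0.93

    def test_r_squared_decreases_with_noise(self):
        rng = np.random.default_rng(4)
        fdp = rng.uniform(3, 110, 300)
        r2 = []
        for sd in (5.0, 20.0, 60.0):
            fbg = 132.905 - 0.6613 * fdp + rng.normal(0, sd, 300)
            c = make_cohort({"fdp": fdp, "fbg": fbg}, [True] * 30 + [False] * 270)
            r2.append(fit_alpha_on_beta(c).r_squared)
        assert r2[0] > r2[1] > r2[2]

    def test_constant_fdp_rejected(self):
        c = make_cohort({"fdp": np.full(10, 50.0)}, [True] * 3 + [False] * 7)
        with pytest.raises(ValueError):
            fit_alpha_on_beta(c)


class _RampPlane:
    def __call__(self, a, b):
        return np.clip((np.asarray(b, float) - 75.0 + 0.5), 0.0, 1.0)


class TestFdpCriterion:
    REG = SimpleRegression.from_coefficients("fbg", ("beta",), (132.905, -0.6613))

    def test_ramp_plane_recovers_the_threshold(self):
        crit = fdp_criterion(_RampPlane(), self.REG, tol=1e-6)
        assert crit.threshold == pytest.approx(75.0, abs=1e-5)

    def test_composed_logistic_matches_the_algebraic_root(self):
        k, x0 = 0.25, 80.0

        def plane(a, b):
            # depends on both anchors; along the regression line the
            # composed q(beta) has a closed-form 0.5 crossing
            return 1 / (1 + np.exp(-k * (np.asarray(b, float) - 0.1 * np.asarray(a, float) - x0)))

        # solve beta - 0.1*(b0 + b1*beta) - x0 = 0
        b0, b1 = self.REG.params
        root = (x0 + 0.1 * b0) / (1 - 0.1 * b1)
        crit = fdp_criterion(plane, self.REG, tol=1e-8)
        assert crit.threshold == pytest.approx(root, abs=1e-6)

    def test_no_crossing_returns_absent(self):
        crit = fdp_criterion(lambda a, b: np.full(np.shape(b), 0.4), self.REG)
        assert crit is None

    def test_smallest_crossing_is_returned_for_nonmonotone_planes(self):
        def plane(a, b):
            b = np.asarray(b, float)
            return np.where((b > 40) & (b < 60), 0.9, np.where(b > 100, 0.9, 0.1))

        crit = fdp_criterion(plane, self.REG)
        assert 39.0 <= crit.threshold <= 41.0

    def test_criterion_sits_on_the_2d_boundary_for_every_method(
        self, planes, gated
    ):
        """The 1-D criterion must equal the FDP at which the regression
        curve crosses each method's plane boundary, within grid
        resolution."""
        reg = fit_alpha_on_beta(gated)
        for method, plane in planes.items():
            crit = fdp_criterion(plane, reg, method=method)
            if crit is None:
                continue
            # the probability must cross 0.5 within 2 grid steps of the root
            lo = float(plane(np.asarray(max(float(reg.predict(np.nan, crit.threshold - 2)), 0.0)),
                             np.asarray(crit.threshold - 2)))
            hi = float(plane(np.asarray(max(float(reg.predict(np.nan, crit.threshold + 2)), 0.0)),
                             np.asarray(crit.threshold + 2)))
            assert (lo - 0.5) * (hi - 0.5) <= 0, method
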