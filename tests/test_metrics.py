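"""Performance metrics: confusion-matrix rates against hand-computed
values, rank AUC against an exhaustive pairwise oracle, class mean class
entropy, and whole-report evaluation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from coagplane.metrics import (
    ConfusionMatrix,
    auc,
    class_mean_class_entropy,
    confusion_metrics,
    evaluate_all,
)
from coagplane.partition import reference_partition

from conftest import make_cohort


def brute_force_auc(labels, scores):
    """Exhaustive pairwise oracle: positives vs negatives, ties = 1/2."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    wins = 0.0
    pairs = 0
    for sp in scores[labels]:
        for sn in scores[~labels]:
            wins += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
            pairs += 1
    return wins / pairs


class TestConfusionMetrics:
    def test_reference_svm_row(self):
        row = confusion_metrics(ConfusionMatrix(tp=2, fp=0, fn=1, tn=20))
        assert round(row["kappa"], 4) == 0.7767
        assert round(row["f1"], 4) == 0.8
        assert round(row["accuracy"], 4) == 0.9565
        assert row["ppv"] == 1.0
        assert round(row["sensitivity"], 4) == 0.6667
        assert row["specificity"] == 1.0

    def test_reference_naive_bayes_row(self):
        row = confusion_metrics(ConfusionMatrix(tp=3, fp=1, fn=0, tn=19))
        assert round(row["f1"], 4) == 0.8571
        assert round(row["kappa"], 4) == 0.8321
        assert row["sensitivity"] == 1.0
        assert row["specificity"] == pytest.approx(0.95)

    def test_perfect_matrix(self):
        row = confusion_metrics(ConfusionMatrix(tp=3, fp=0, fn=0, tn=20))
        for key in ("accuracy", "kappa", "f1", "ppv", "sensitivity", "specificity"):
            assert row[key] == 1.0

    def test_binomial_se_rounds_to_the_printed_plus_minus(self):
        r22 = confusion_metrics(ConfusionMatrix(tp=2, fp=0, fn=1, tn=20))
        assert round(r22["accuracy_sd"], 2) == 0.04  # 22/23 correct
        r21 = confusion_metrics(ConfusionMatrix(tp=1, fp=0, fn=2, tn=20))
        assert round(r21["accuracy_sd"], 2) == 0.06  # 21/23 correct

    def test_undefined_rates_reported_absent(self):
        row = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
        assert row["sensitivity"] is None
        assert row["ppv"] is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=1)
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, fp=0, fn=0, tn=0)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_kappa_agrees_with_the_agreement_form(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        cm = ConfusionMatrix(tp, fp, fn, tn)
        row = confusion_metrics(cm)
        y_true = [True] * (tp + fn) + [False] * (fp + tn)
        y_pred = [True] * tp + [False] * fn + [True] * fp + [False] * tn
        if len(set(y_true)) > 1 or len(set(y_pred)) > 1:
            ref = cohen_kappa_score(y_true, y_pred)
            if np.isfinite(ref):
                assert row["kappa"] == pytest.approx(ref, abs=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_hand_case(self):
        assert auc([1, 0, 1, 0], [0.9, 0.4, 0.35, 0.8]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.4])

    @given(st.data())
    def test_matches_exhaustive_oracle_and_sklearn(self, data):
        n = data.draw(st.integers(4, 50))
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False, width=16), min_size=n, max_size=n
            )
        )
        mine = auc(labels, scores)
        assert mine == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)
        assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)


class TestClassMeanClassEntropy:
    def test_confident_correct_predictions_give_zero(self):
        labels = [True, False, False]
        proba = np.array([[1e-15, 1 - 1e-15], [1 - 1e-15, 1e-15], [1 - 1e-15, 1e-15]])
        assert class_mean_class_entropy(labels, proba) <= 1e-10

    def test_uniform_probabilities_give_ln2(self):
        labels = [True, False, True, False]
        proba = np.full((4, 2), 0.5)
        assert class_mean_class_entropy(labels, proba) == pytest.approx(np.log(2))

    def test_hand_built_four_record_case(self):
        labels = [True, True, False, False]
        proba = np.array([[0.2, 0.8], [0.5, 0.5], [0.9, 0.1], [0.6, 0.4]])
        expect = 0.5 * (
            (-np.log(0.8) - np.log(0.5)) / 2 + (-np.log(0.9) - np.log(0.6)) / 2
        )
        assert class_mean_class_entropy(labels, proba) == pytest.approx(expect, abs=1e-12)

    def test_zero_probability_clamped_not_fatal(self):
        labels = [True, False]
        proba = np.array([[1.0, 0.0], [1.0, 0.0]])
        value = class_mean_class_entropy(labels, proba)
        assert np.isfinite(value) and value > 0


class _MajorityClassifier:
    """Always predicts non-hematuria with certainty 0.9."""

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.tile([0.9, 0.1], (n, 1))


class _RandomClassifier:
    def __init__(self, seed):
        self.rng = np.random.default_rng(seed)

    def predict_proba(self, X):
        p = self.rng.random(np.asarray(X).shape[0])
        return np.column_stack([1 - p, p])


class TestEvaluateAll:
    def test_majority_classifier_on_the_3_20_cohort(self, gated, canonical_partition):
        report = evaluate_all({"maj": _MajorityClassifier()}, gated, canonical_partition)
        row = report.loc["maj"]
        assert row["accuracy"] == pytest.approx(20 / 23)
        assert round(row["accuracy"], 4) == 0.8696
        assert row["sensitivity"] == 0.0
        assert row["kappa"] == 0.0

    def test_svm_on_separable_cohort_scores_perfectly(self):
        from coagplane.boundaries import train_classifier
        from coagplane.reference import SVM_RULE
        from coagplane.simulate import generate_separable_cohort

        c = generate_separable_cohort(SVM_RULE, 30, 30, margin=10.0, seed=1)
        part = reference_partition()
        clf = train_classifier(c, part, "svm", seed=0)
        report = evaluate_all({"svm": clf}, c, part)
        row = report.loc["svm"]
        for key in ("accuracy", "auc", "kappa", "f1", "ppv", "sensitivity", "specificity"):
            assert row[key] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_rates_stay_in_the_unit_interval_for_random_classifiers(
        self, seed, gated, canonical_partition
    ):
        report = evaluate_all(
            {"rand": _RandomClassifier(seed)}, gated, canonical_partition
        )
        row = report.loc["rand"]
        for key in ("accuracy", "auc", "f1", "ppv", "sensitivity", "specificity"):
            if row[key] is not None and np.isfinite(float(row[key] or np.nan)):
                assert 0.0 <= row[key] <= 1.0
        assert -1.0 <= row["kappa"] <= 1.0

    def test_six_method_report_shape_and_bounds(self, trained, gated, canonical_partition):
        report = evaluate_all(trained, gated, canonical_partition)
        assert list(report.index) == list(trained)
        assert (report["accuracy"] >= 0.0).all() and (report["accuracy"] <= 1.0).all()
        assert (report["auc"] >= 0.5).all()
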