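"""Forest training, multiclass AUC, repeated CV and OOB permutation importance."""

import numpy as np
import pytest

from moipred.classifier import (
    EvaluationReport,
    class_precision_recall,
    confusion_matrix,
    cross_validate,
    multiclass_auc,
    permutation_importance,
    precision,
    recall,
    train,
)
from moipred.errors import ContractError, ValidationError
from moipred.features import CLASSES, FeatureMatrix
from moipred.fixtures import make_classification_matrix


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "func,a,b,expected",
        [
            (precision, 8, 2, 0.8),
            (recall, 8, 2, 0.8),
            (precision, 0, 0, None),
            (recall, 0, 0, None),
            (precision, 0, 5, 0.0),
        ],
    )
    def test_formula(self, func, a, b, expected):
        assert func(a, b) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            precision(-1, 0)

    def test_matches_brute_force_confusion_counting(self):
        """Per-class precision/recall from the confusion matrix equal direct
        counting over random truth/prediction pairs."""
        rng = np.random.default_rng(12)
        classes = list(CLASSES)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            truth = rng.choice(classes, size=n)
            pred = rng.choice(classes, size=n)
            counts = confusion_matrix(truth, pred, classes)
            metrics = class_precision_recall(counts, classes)
            for c in classes:
                tp = int(np.sum((truth == c) & (pred == c)))
                fp = int(np.sum((truth != c) & (pred == c)))
                fn = int(np.sum((truth == c) & (pred != c)))
                assert metrics[c]["precision"] == precision(tp, fp)
                assert metrics[c]["recall"] == recall(tp, fn)


class TestMulticlassAUC:
    def test_perfect_separation_is_one(self):
        labels = ["benign"] * 5 + ["dominant"] * 5 + ["recessive"] * 5
        scores = np.zeros((15, 3))
        for i, lab in enumerate(labels):
            scores[i, CLASSES.index(lab)] = 1.0
        assert multiclass_auc(scores, labels) == pytest.approx(1.0)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(0)
        n = 1000
        scores = rng.dirichlet(np.ones(3), size=n)
        labels = rng.choice(list(CLASSES), size=n)
        assert multiclass_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_two_class_equals_pairwise_comparison_oracle(self):
        """On two classes the statistic equals exhaustive pair counting."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            labels = rng.choice(["benign", "dominant"], size=n)
            if len(set(labels)) < 2:
                continue
            p = rng.random(n)
            scores = np.column_stack([p, 1 - p])
            # oracle: average of pair comparisons in both score columns
            def pair_auc(col, pos):
                wins = ties = total = 0
                for i in range(n):
                    for j in range(n):
                        if labels[i] == pos and labels[j] != pos:
                            total += 1
                            if scores[i, col] > scores[j, col]:
                                wins += 1
                            elif scores[i, col] == scores[j, col]:
                                ties += 1
                return (wins + ties / 2) / total

            expected = (pair_auc(0, "benign") + pair_auc(1, "dominant")) / 2
            got = multiclass_auc(scores, labels, classes=["benign", "dominant"])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_reference_pairwise_implementation(self):
        """Independent cross-check against the one-vs-one ROC-AUC average."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        n = 300
        scores = rng.dirichlet(np.ones(3), size=n)
        labels = rng.choice(list(CLASSES), size=n, p=[0.5, 0.2, 0.3])
        ours = multiclass_auc(scores, labels)
        ref = roc_auc_score(labels, scores, multi_class="ovo", labels=list(CLASSES))
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.random((100, 3))
        labels = rng.choice(list(CLASSES), size=100)
        transformed = np.column_stack(
            [np.exp(scores[:, 0]), scores[:, 1] ** 3, np.log1p(scores[:, 2])]
        )
        assert multiclass_auc(scores, labels) == pytest.approx(
            multiclass_auc(transformed, labels), abs=1e-12
        )

    def test_empty_class_rejected(self):
        scores = np.ones((3, 3)) / 3
        with pytest.raises(ValidationError, match="no rows"):
            multiclass_auc(scores, ["benign"] * 3, classes=list(CLASSES))


class TestTrain:
    def test_separated_classes_fit_with_high_accuracy(self):
        m = make_classification_matrix(n_per_class=60, delta=3.0, seed=1)
        model = train(m, n_trees=100, seed=2)
        acc = np.mean(np.asarray(model.predict(m)) == np.asarray(m.labels))
        assert acc > 0.95

    def test_conflicting_duplicate_rows_give_prior_probabilities(self):
        """With identical rows and conflicting labels the vote fractions
        approach the class priors."""
        values = np.zeros((90, 2))
        labels = ["benign"] * 30 + ["dominant"] * 30 + ["recessive"] * 30
        m = FeatureMatrix(
            row_ids=[(f"r{i}",) for i in range(90)],
            columns=["a", "b"],
            values=values,
            labels=labels,
        )
        model = train(m, n_trees=300, seed=0)
        proba = model.predict_proba(np.zeros((1, 2)))
        assert np.allclose(proba, 1 / 3, atol=0.12)

    def test_same_seed_identical_predictions(self):
        m = make_classification_matrix(n_per_class=40, delta=1.0, seed=3)
        p1 = train(m, n_trees=50, seed=9).predict_proba(m)
        p2 = train(m, n_trees=50, seed=9).predict_proba(m)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        m = make_classification_matrix(n_per_class=10, seed=0)
        m.labels = ["benign"] * m.n_rows
        with pytest.raises(ValidationError, match=">=2 classes"):
            train(m, n_trees=10)

    def test_probabilities_sum_to_one_exactly(self):
        m = make_classification_matrix(n_per_class=50, delta=0.5, seed=4)
        proba = train(m, n_trees=70, seed=1).predict_proba(m)
        assert np.abs(proba.sum(axis=1) - 1.0).max() <= 1e-9

    def test_catalogue_mismatch_rejected(self):
        m = make_classification_matrix(n_per_class=20, seed=5)
        model = train(m, n_trees=10, seed=0)
        other = m.copy()
        other.columns = list(other.columns[::-1])
        with pytest.raises(ContractError, match="columns"):
            model.predict_proba(other)


class TestCrossValidate:
    def test_each_row_scored_once_per_repeat(self):
        """Fold confusion counts sum to the full row count."""
        m = make_classification_matrix(n_per_class=30, delta=2.0, seed=6)
        report = cross_validate(m, folds=5, repeats=2, seed=3, n_trees=30)
        for rep in report.repeats:
            assert rep.confusion.sum() == m.n_rows

    def test_deterministic_given_seed(self):
        m = make_classification_matrix(n_per_class=30, delta=1.0, seed=7)
        r1 = cross_validate(m, folds=5, repeats=2, seed=5, n_trees=30)
        r2 = cross_validate(m, folds=5, repeats=2, seed=5, n_trees=30)
        assert [a.auc for a in r1.repeats] == [b.auc for b in r2.repeats]
        assert all(
            np.array_equal(a.confusion, b.confusion)
            for a, b in zip(r1.repeats, r2.repeats)
        )

    def test_separated_fixture_reaches_high_auc(self):
        m = make_classification_matrix(n_per_class=100, delta=3.0, seed=8)
        report = cross_validate(m, folds=10, repeats=1, seed=1, n_trees=100)
        assert report.mean_auc >= 0.95

    def test_auc_nondecreasing_in_separation(self):
        aucs = []
        for delta in (0.0, 1.0, 3.0):
            m = make_classification_matrix(n_per_class=60, delta=delta, seed=10)
            aucs.append(
                cross_validate(m, folds=5, repeats=1, seed=2, n_trees=60).mean_auc
            )
        assert aucs[0] == pytest.approx(0.5, abs=0.1)
        assert aucs[0] < aucs[1] < aucs[2]

    def test_class_smaller_than_folds_rejected(self):
        m = make_classification_matrix(n_per_class=5, delta=1.0, seed=11)
        with pytest.raises(ValidationError, match="fewer rows"):
            cross_validate(m, folds=10, repeats=1, n_trees=10)

    def test_summary_table_shape(self):
        m = make_classification_matrix(n_per_class=30, delta=2.0, seed=12)
        report = cross_validate(m, folds=3, repeats=2, seed=0, n_trees=20)
        summary = report.summary()
        assert set(summary["metric"]) == {"precision", "recall", "multiclass_auc"}
        assert (summary["min"] <= summary["max"]).all()


@pytest.fixture(scope="module")
def one_signal_model():
    rng = np.random.default_rng(13)
    n = 300
    labels = ["benign", "dominant", "recessive"] * (n // 3)
    signal = np.array([CLASSES.index(l) * 2.0 for l in labels]) + rng.normal(0, 0.5, n)
    values = np.column_stack(
        [signal, rng.normal(size=n), np.full(n, 7.0)]  # signal, noise, constant
    )
    m = FeatureMatrix(
        row_ids=[(f"r{i}",) for i in range(n)],
        columns=["signal", "noise", "constant"],
        values=values,
        labels=labels,
    )
    return train(m, n_trees=150, seed=3)


class TestPermutationImportance:
    def test_sole_informative_feature_ranks_first(self, one_signal_model):
        imp = permutation_importance(one_signal_model, seed=1).set_index("feature")
        assert imp["importance"].idxmax() == "signal"

    def test_constant_feature_importance_is_zero(self, one_signal_model):
        imp = permutation_importance(one_signal_model, seed=1).set_index("feature")
        assert imp.loc["constant", "importance"] == 0.0
        assert imp.loc["constant", "mean_decrease_accuracy"] == 0.0

    def test_noise_feature_importance_near_zero(self, one_signal_model):
        imp = permutation_importance(one_signal_model, seed=1).set_index("feature")
        assert abs(imp.loc["noise", "importance"]) < 2.0
        assert (
            imp.loc["signal", "importance"] > 5 * abs(imp.loc["noise", "importance"])
            or imp.loc["noise", "importance"] == 0
        )

    def test_signal_features_outrank_noise(self):
        m = make_classification_matrix(
            n_per_class=100, n_signal=3, n_noise=10, delta=1.0, seed=14
        )
        model = train(m, n_trees=150, seed=5)
        imp = permutation_importance(model, seed=2)
        top = list(imp["feature"][:3])
        assert all(f.startswith("signal_") for f in top)
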