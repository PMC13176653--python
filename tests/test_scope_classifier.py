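"""Classifier training, pruning, evaluation and cross-validation."""

import numpy as np
import pytest

from ifnscope import scope_classifier as sc
from ifnscope.errors import (
    DegenerateLabelsError,
    EmptyEvalError,
    FeatureShapeError,
    StratificationError,
)


def brute_force_auc(labels, scores):
    """Tie-adjusted pairwise (Mann-Whitney) statistic, the AUC oracle."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def toy_dataset(flip=False):
    X = np.array([[1.0]] * 20 + [[-1.0]] * 20)
    y = np.array([True] * 20 + [False] * 20)
    if flip:
        y = ~y
    return sc.LabeledDataset(X, y)


class TestFitLogistic:
    def test_separable_toy_fits_perfectly(self):
        model = sc.fit_logistic(toy_dataset(), seed=3)
        assert model.coefficients[0] > 0
        labels, _ = sc.predict(model, toy_dataset().X)
        assert (labels == toy_dataset().y).all()

    def test_label_flip_negates_coefficient(self):
        a = sc.fit_logistic(toy_dataset(), seed=3)
        b = sc.fit_logistic(toy_dataset(flip=True), seed=3)
        assert a.coefficients[0] == pytest.approx(-b.coefficients[0], abs=1e-6)
        assert a.intercept == pytest.approx(-b.intercept, abs=1e-6)

    def test_gaussian_blobs_recover_bayes_direction(self, rng):
        """With shared covariance the optimal boundary is the LDA direction."""
        mean_pos, mean_neg = np.array([1.0, 0.5]), np.array([-1.0, -0.5])
        X = np.vstack(
            [rng.normal(mean_pos, 1.0, (200, 2)), rng.normal(mean_neg, 1.0, (200, 2))]
        )
        y = np.array([True] * 200 + [False] * 200)
        model = sc.fit_logistic(sc.LabeledDataset(X, y), seed=0)
        # undo the internal standardisation to compare directions in raw space
        w = model.coefficients / model.feature_scales
        bayes = mean_pos - mean_neg  # Σ = I ⇒ direction ∝ Δμ
        cosine = w @ bayes / (np.linalg.norm(w) * np.linalg.norm(bayes))
        assert cosine > 0.98

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            sc.fit_logistic(sc.LabeledDataset(np.ones((5, 2)), np.ones(5, dtype=bool)))


class TestSelectFeatures:
    @pytest.mark.parametrize(
        "coefficients, expected",
        [
            ((3.0, 1.0, 2.0), (True, False, True)),   # mean 2, boundary keeps 2
            ((1.0, 1.0, 1.0), (True, True, True)),    # |ω| = mean ⇒ kept
            ((-5.0, 0.1), (True, False)),             # absolute values compared
        ],
    )
    def test_mean_magnitude_rule(self, coefficients, expected):
        model = sc.ScopeModel(
            coefficients=np.array(coefficients),
            intercept=0.0,
            selected=np.ones(len(coefficients), dtype=bool),
        )
        assert tuple(sc.select_features(model)) == expected

    def test_all_zero_rejected(self):
        model = sc.ScopeModel(np.zeros(3), 0.0, np.ones(3, dtype=bool))
        with pytest.raises(sc.EmptyModelError):
            sc.select_features(model)


class TestTrainScope:
    def test_informative_support_retained(self, rng):
        """Only features 0..9 carry signal; pruning must keep them all."""
        n, d = 2000, 80
        X = rng.normal(size=(n, d))
        beta = np.zeros(d)
        beta[:10] = 1.5
        y = rng.random(n) < 1.0 / (1.0 + np.exp(-(X @ beta)))
        model = sc.train_scope(sc.LabeledDataset(X, y), seed=1)
        assert model.metadata["pre_pruning_dimension"] == 80
        assert model.selected[:10].all()
        assert 10 <= model.selected.sum() < 80

    def test_pruning_disabled_matches_plain_fit(self):
        ds = toy_dataset()
        plain = sc.fit_logistic(ds, seed=5)
        unpruned = sc.train_scope(ds, seed=5, prune=False)
        assert np.allclose(plain.coefficients, unpruned.coefficients)
        assert plain.selected.all() and unpruned.selected.all()

    def test_serialized_models_are_byte_identical(self, training_set):
        a = sc.train_scope(training_set, seed=7)
        b = sc.train_scope(training_set, seed=7)
        assert a.to_json() == b.to_json()
        restored = sc.ScopeModel.from_json(a.to_json())
        assert np.allclose(
            restored.predict_proba(training_set.X), a.predict_proba(training_set.X)
        )


class TestEvaluate:
    def test_direct_substitution_of_counts(self):
        labels = [True] * 10 + [False] * 10
        scores = [0.9] * 8 + [0.1] * 2 + [0.9] * 2 + [0.1] * 8
        report = sc.evaluate(labels, scores)
        assert (report.tp, report.fp, report.fn, report.tn) == (8, 2, 2, 8)
        for metric in ("precision", "recall", "f1", "accuracy"):
            assert getattr(report, metric) == pytest.approx(0.8)

    def test_perfect_ranking_has_unit_auc(self):
        report = sc.evaluate([True] * 5 + [False] * 5, [0.9] * 5 + [0.2] * 5)
        assert report.auc == 1.0

    def test_auc_equals_pairwise_statistic(self, rng):
        for _ in range(5):
            labels = rng.random(200) < 0.4
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(200), 2)  # rounding forces ties
            report = sc.evaluate(labels, scores)
            assert report.auc == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)

    def test_metrics_recomputable_from_counts(self, rng):
        labels = rng.random(300) < 0.3
        scores = rng.random(300)
        r = sc.evaluate(labels, scores)
        assert r.precision == pytest.approx(r.tp / (r.tp + r.fp), abs=1e-12)
        assert r.recall == pytest.approx(r.tp / (r.tp + r.fn), abs=1e-12)
        assert r.f1 == pytest.approx(
            2 * r.precision * r.recall / (r.precision + r.recall), abs=1e-12
        )
        assert r.accuracy == pytest.approx(
            (r.tp + r.tn) / (r.tp + r.fp + r.tn + r.fn), abs=1e-12
        )

    def test_undefined_precision_flagged_as_zero(self):
        report = sc.evaluate([True, False], [0.1, 0.2])
        assert report.precision == 0.0
        assert "undefined_precision" in report.flags

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyEvalError):
            sc.evaluate([], [])


class TestCrossValidate:
    def _dataset(self, rng, n=100):
        X = rng.normal(size=(n, 4))
        y = np.array([True, False] * (n // 2))
        X[y, 0] += 3.0
        return sc.LabeledDataset(X, y, tuple(f"s{i}" for i in range(n)))

    def test_every_example_held_out_exactly_once(self, rng):
        ds = self._dataset(rng)
        report = sc.cross_validate(ds, folds=5, seed=2)
        held_out = sum(r.tp + r.fp + r.tn + r.fn for r in report.per_fold)
        assert held_out == 100
        assert report.tp + report.fp + report.tn + report.fn == 100

    def test_same_seed_reproduces_metrics(self, rng):
        ds = self._dataset(rng)
        a = sc.cross_validate(ds, folds=5, seed=9)
        b = sc.cross_validate(ds, folds=5, seed=9)
        assert (a.tp, a.fp, a.tn, a.fn, a.f1, a.auc) == (b.tp, b.fp, b.tn, b.fn, b.f1, b.auc)

    def test_family_separation_at_five_percent_mutation(self, training_set):
        """Synthetic IFN family vs shuffled neighbours: mean F1 >= 0.90."""
        report = sc.cross_validate(training_set, folds=5, seed=11)
        assert report.f1 >= 0.90
        assert np.mean([r.f1 for r in report.per_fold]) >= 0.90

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([True] * 3 + [False] * 7)
        with pytest.raises(StratificationError):
            sc.cross_validate(sc.LabeledDataset(X, y), folds=5)


class TestPredict:
    def test_zero_score_gives_half_probability(self):
        model = sc.ScopeModel(np.zeros(3), 0.0, np.ones(3, dtype=bool))
        _, probs = sc.predict(model, np.zeros((2, 3)))
        assert np.allclose(probs, 0.5)

    def test_dimension_mismatch(self):
        model = sc.ScopeModel(np.ones(3), 0.0, np.ones(3, dtype=bool))
        with pytest.raises(FeatureShapeError):
            sc.predict(model, np.zeros((2, 4)))
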