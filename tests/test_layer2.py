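import itertools

import numpy as np
import pytest
from sklearn.feature_selection import f_regression as sk_f_regression

from abtriage.encoding import build_layout
from abtriage.errors import DimensionMismatch, SingleClassLabels, TooFewSamples, UnknownIndex
from abtriage.layer2 import (
    FeatureSelection,
    Layer2Model,
    cross_validate,
    f_regression_rank,
    feature_positions,
    mcc,
    predict,
    select_k,
    train_classifier,
)
from abtriage.synthetic_fixtures import LabeledFeatureSpec, generate_labeled_features


class TestFRegressionRank:
    def test_hand_calculation(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        _, F, _ = f_regression_rank(X, y)
        assert F[0] == pytest.approx(8.0)

    def test_constant_feature_scores_zero_and_ranks_last(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        y = (rng.random(20) > 0.5).astype(int)
        y[:2] = [0, 1]
        order, F, _ = f_regression_rank(X, y)
        assert F[1] == 0.0
        assert order[-1] == 1

    def test_perfect_feature_ranks_first(self, rng):
        y = np.array([0, 1] * 10)
        X = np.column_stack([rng.normal(size=20), y.astype(float)])
        order, F, p = f_regression_rank(X, y)
        assert order[0] == 1
        assert np.isinf(F[1]) and p[1] == 0.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(SingleClassLabels):
            f_regression_rank(rng.normal(size=(10, 3)), np.zeros(10))

    def test_matches_sklearn_oracle(self, rng):
        X = rng.normal(size=(20, 30))
        y = (rng.random(20) > 0.5).astype(int)
        y[:2] = [0, 1]
        _, F, p = f_regression_rank(X, y)
        F_sk, p_sk = sk_f_regression(X, y)
        np.testing.assert_allclose(F, F_sk, rtol=1e-8)
        np.testing.assert_allclose(p, p_sk, rtol=1e-8, atol=1e-12)

    def test_rank_agreement_with_brute_force_sort(self, rng):
        X = rng.normal(size=(20, 30))
        y = (rng.random(20) > 0.5).astype(int)
        y[:2] = [0, 1]
        order, F, _ = f_regression_rank(X, y)
        brute = sorted(range(30), key=lambda j: (-F[j], j))
        assert list(order) == brute


class TestSelectK:
    def test_k1_picks_perfect_feature(self, rng):
        y = np.array([0, 1] * 10)
        X = np.column_stack([rng.normal(size=20), y.astype(float)])
        assert select_k(X, y, 1).indices == (1,)

    def test_k_at_least_n_features_is_identity_set(self, rng):
        X = rng.normal(size=(12, 5))
        y = np.array([0, 1] * 6)
        sel = select_k(X, y, 99)
        assert sorted(sel.indices) == list(range(5))

    def test_tie_break_lowest_index_first(self):
        y = np.array([0, 0, 1, 1], dtype=float)
        X = np.column_stack([y, y, y])  # three identical perfect features
        sel = select_k(X, y.astype(int), 2)
        assert sel.indices == (0, 1)

    def test_idempotent(self, rng):
        X = rng.normal(size=(20, 10))
        y = (rng.random(20) > 0.5).astype(int)
        y[:2] = [0, 1]
        assert select_k(X, y, 4) == select_k(X, y, 4)


class TestTrainPredict:
    def separable(self, rng, n=60):
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 4))
        X[:, 0] += 6.0 * y
        return X, y

    @pytest.mark.parametrize("kind", ["linear_svc", "ridge", "logistic"])
    def test_separable_training_mcc_one(self, rng, kind):
        X, y = self.separable(rng)
        model = train_classifier(X, y, kind=kind, seed=0)
        labels, _ = predict(model, X)
        tp = int(((labels == 1) & (y == 1)).sum())
        fp = int(((labels == 1) & (y == 0)).sum())
        tn = int(((labels == 0) & (y == 0)).sum())
        fn = int(((labels == 0) & (y == 1)).sum())
        assert mcc(tp, fp, tn, fn) == pytest.approx(1.0)

    def test_label_inversion_negates_weights(self, rng):
        X, y = self.separable(rng)
        m1 = train_classifier(X, y, kind="ridge", seed=0)
        m2 = train_classifier(X, 1 - y, kind="ridge", seed=0)
        np.testing.assert_allclose(m1.weights, -m2.weights, atol=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(SingleClassLabels):
            train_classifier(rng.normal(size=(10, 3)), np.ones(10))

    def test_threshold_monotonicity(self, rng):
        X, y = self.separable(rng)
        X[:, 0] += rng.normal(scale=3.0, size=len(y))  # make probs spread out
        model = train_classifier(X, y, seed=0)
        at_05, _ = predict(model, X, threshold=0.5)
        at_08, _ = predict(model, X, threshold=0.8)
        assert set(np.nonzero(at_08)[0]) <= set(np.nonzero(at_05)[0])

    def test_empty_input(self, rng):
        X, y = self.separable(rng)
        model = train_classifier(X, y, seed=0)
        labels, probs = predict(model, np.empty((0, 4)))
        assert labels.size == 0 and probs.size == 0

    def test_dimension_mismatch(self, rng):
        X, y = self.separable(rng)
        model = train_classifier(X, y, seed=0)
        with pytest.raises(DimensionMismatch):
            predict(model, rng.normal(size=(3, 5)))

    def test_json_round_trip(self, rng):
        X, y = self.separable(rng)
        model = train_classifier(X, y, seed=0, threshold=0.8)
        clone = Layer2Model.from_json(model.to_json())
        np.testing.assert_allclose(clone.weights, model.weights)
        assert clone.threshold == 0.8
        _, p1 = predict(model, X)
        _, p2 = predict(clone, X)
        np.testing.assert_allclose(p1, p2)


class TestMcc:
    def test_perfect(self):
        assert mcc(10, 0, 10, 0) == 1.0

    def test_derived_value(self):
        assert mcc(45, 5, 45, 5) == pytest.approx(0.8)

    def test_all_one_class_convention(self):
        assert mcc(20, 20, 0, 0) == 0.0

    def test_exhaustive_small_tables_match_formula(self):
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom ** 0.5
            assert mcc(tp, fp, tn, fn) == pytest.approx(expected)


class TestCrossValidate:
    def test_partition_property(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.array([0, 1] * 20)
        metrics = cross_validate(X, y, k=3, folds=10, seed=1)
        total = sum(r["tp"] + r["fp"] + r["tn"] + r["fn"] for r in metrics.per_fold)
        assert total == 40

    def test_separable_fixture_high_mcc(self):
        X, y, _ = generate_labeled_features(LabeledFeatureSpec(
            n=200, d=50, k_informative=5, effect=3.0, seed=0))
        metrics = cross_validate(X, y, k=10, folds=10, seed=0)
        assert metrics.mean_mcc >= 0.95

    def test_too_few_samples(self, rng):
        with pytest.raises(TooFewSamples):
            cross_validate(rng.normal(size=(5, 3)), np.array([0, 1, 0, 1, 0]),
                           k=2, folds=10)

    def test_null_labels_mcc_near_zero_across_seeds(self):
        means = []
        for seed in range(20):
            X, y, _ = generate_labeled_features(LabeledFeatureSpec(
                n=60, d=40, k_informative=0, effect=0.0, seed=seed))
            metrics = cross_validate(X, y, k=10, folds=5, seed=seed)
            means.append(metrics.mean_mcc)
        assert abs(float(np.mean(means))) < 0.15

    def test_selection_leakage_regression(self):
        """Selection outside folds on high-dimensional noise inflates CV MCC;
        selection inside folds must not."""
        inside, outside = [], []
        for seed in range(5):
            X, y, _ = generate_labeled_features(LabeledFeatureSpec(
                n=60, d=500, k_informative=0, effect=0.0, seed=100 + seed))
            inside.append(cross_validate(X, y, k=50, folds=5, seed=seed).mean_mcc)
            outside.append(cross_validate(X, y, k=50, folds=5, seed=seed,
                                          select_outside_folds=True).mean_mcc)
        assert abs(float(np.mean(inside))) < 0.2
        assert float(np.mean(outside)) > float(np.mean(inside)) + 0.2

    def test_planted_feature_recovery(self):
        hits = 0
        for seed in range(10):
            X, y, informative = generate_labeled_features(LabeledFeatureSpec(
                n=200, d=1000, k_informative=5, effect=2.0, seed=seed))
            sel = select_k(X, y, 50)
            hits += len(set(informative) & set(sel.indices)) >= 4
        assert hits == 10


class TestFeaturePositions:
    def test_counts_sum_to_k(self, rng):
        layout = build_layout(4)
        sel = FeatureSelection(k=10, indices=tuple(range(10)),
                               f_scores=(1.0,) * 10, p_values=(0.5,) * 10)
        attribution = feature_positions(sel, layout)
        assert attribution.total() == 10

    def test_single_slot_bar(self):
        layout = build_layout(4)
        sel = FeatureSelection(k=4, indices=(0, 1, 2, 3),
                               f_scores=(1.0,) * 4, p_values=(0.5,) * 4)
        attribution = feature_positions(sel, layout)
        assert attribution.counts == {("heavy", "H1"): 4}

    def test_unknown_index(self):
        layout = build_layout(1)
        sel = FeatureSelection(k=1, indices=(10**6,), f_scores=(1.0,),
                               p_values=(0.5,))
        with pytest.raises(UnknownIndex):
            feature_positions(sel, layout)

    def test_planted_slot_recovery(self, rng):
        """Features planted on one grid slot dominate the attribution."""
        layout = build_layout(8)
        slot_indices = tuple(range(40 * 8, 41 * 8))  # all channels of slot 40
        y = np.array([0, 1] * 30)
        X = rng.normal(size=(60, len(layout)) * 0)  # placeholder, built below
        X = rng.normal(size=(60, 60 * 8))
        # use a reduced layout-compatible matrix: plant signal on slot 40
        for j in slot_indices:
            X[:, j] += 3.0 * y
        sel = select_k(X, y, 8)
        attribution = feature_positions(sel, layout)
        top_slot = max(attribution.counts, key=attribution.counts.get)
        assert top_slot == ("heavy", build_layout(1).slots[40])
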