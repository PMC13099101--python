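"""Boosted-tree mechanics: Newton leaf weights, regularization limits,
exact split search, loss monotonicity, CV grid search and metrics."""

import numpy as np
import pytest

from ecopipe.gbdt import (
    GBDTModel,
    TrainConfig,
    auc_rank,
    evaluate_classifier,
    fit_gbdt,
    grid_search_cv,
    log_loss,
    make_pair_labels,
    predict_margin,
    predict_proba,
    stratified_kfold,
)


def toy_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 3))
    y = (X[:, 0] + 0.3 * rng.standard_normal(n) > 0.5).astype(int)
    return X, y


class TestFitMechanics:
    def test_balanced_depth0_first_leaf_zero(self):
        rng = np.random.default_rng(0)
        X = rng.random((100, 2))
        y = np.array([0, 1] * 50)
        model = fit_gbdt(X, y, TrainConfig(n_estimators=1, max_depth=0, reg_lambda=0.0))
        assert model.trees[0].leaf_values()[0] == pytest.approx(0.0, abs=1e-12)

    def test_huge_lambda_shrinks_leaves_to_zero(self):
        X, y = toy_data()
        model = fit_gbdt(X, y, TrainConfig(n_estimators=20, reg_lambda=1e9))
        for tree in model.trees:
            assert np.max(np.abs(tree.value)) < 1e-6
        p = predict_proba(model, X)
        assert np.allclose(p, 0.5, atol=1e-5)  # stays at the base rate margin

    def test_depth1_split_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        x = rng.random(60)
        y = (x > 0.55).astype(int)
        X = x[:, None]
        lam = 1.0
        model = fit_gbdt(X, y, TrainConfig(n_estimators=1, max_depth=1, reg_lambda=lam))
        tree = model.trees[0]
        chosen = float(tree.threshold[0])
        # brute force over all candidate midpoints with the Newton gain
        p = np.full(len(y), 0.5)
        g, h = p - y, p * (1 - p)
        xs = np.unique(x)
        best_gain, best_thr = -np.inf, None
        for a, b in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (a + b)
            left = x < thr
            gl, hl = g[left].sum(), h[left].sum()
            gr, hr = g[~left].sum(), h[~left].sum()
            gain = gl**2 / (hl + lam) + gr**2 / (hr + lam) - (gl + gr) ** 2 / (hl + hr + lam)
            if gain > best_gain + 1e-15:
                best_gain, best_thr = gain, thr
        assert chosen == pytest.approx(best_thr)

    def test_training_loss_monotone_nonincreasing(self):
        X, y = toy_data(n=300, seed=1)
        cfg = TrainConfig(n_estimators=60, max_depth=2, subsample=1.0)
        model = fit_gbdt(X, y, cfg)
        margin = np.full(len(y), model.base_margin)
        losses = [log_loss(y, 1 / (1 + np.exp(-margin)))]
        for tree in model.trees:
            margin = margin + cfg.learning_rate * tree.predict(X)
            losses.append(log_loss(y, 1 / (1 + np.exp(-margin))))
        assert all(b <= a + 1e-12 for a, b in zip(losses[:-1], losses[1:]))

    def test_single_class_constant_model(self):
        X = np.random.default_rng(0).random((30, 2))
        with pytest.warns(UserWarning):
            model = fit_gbdt(X, np.ones(30), TrainConfig(n_estimators=5))
        assert len(model.trees) == 0
        assert np.all(predict_proba(model, X) > 0.99)

    def test_seeded_subsampling_reproducible(self):
        X, y = toy_data()
        cfg = TrainConfig(n_estimators=10, subsample=0.7, colsample_bytree=0.7, seed=4)
        m1, m2 = fit_gbdt(X, y, cfg), fit_gbdt(X, y, cfg)
        np.testing.assert_array_equal(predict_margin(m1, X), predict_margin(m2, X))


class TestPredict:
    def test_empty_model_is_half(self):
        model = GBDTModel(config=TrainConfig(), base_margin=0.0, n_features=2)
        assert np.allclose(predict_proba(model, np.zeros((3, 2))), 0.5)

    def test_margins_additive_over_trees(self):
        X, y = toy_data()
        model = fit_gbdt(X, y, TrainConfig(n_estimators=8))
        part1 = GBDTModel(config=model.config, trees=model.trees[:3],
                          base_margin=model.base_margin, n_features=3)
        part2 = GBDTModel(config=model.config, trees=model.trees[3:],
                          base_margin=0.0, n_features=3)
        total = predict_margin(part1, X) + predict_margin(part2, X)
        np.testing.assert_allclose(total, predict_margin(model, X), atol=1e-12)

    def test_hand_traced_two_tree_model(self):
        # tree 1: x0 < 0.5 -> -1 else +2 ; tree 2: x1 < 0.3 -> +0.5 else -0.5
        from ecopipe.gbdt import Tree, _TreeNode

        t1 = Tree.from_nodes([
            _TreeNode(feature=0, threshold=0.5, left=1, right=2),
            _TreeNode(value=-1.0), _TreeNode(value=2.0),
        ])
        t2 = Tree.from_nodes([
            _TreeNode(feature=1, threshold=0.3, left=1, right=2),
            _TreeNode(value=0.5), _TreeNode(value=-0.5),
        ])
        model = GBDTModel(config=TrainConfig(learning_rate=0.1), trees=[t1, t2],
                          base_margin=0.2, n_features=2)
        X = np.array([[0.4, 0.1], [0.9, 0.9]])
        expect = 0.2 + 0.1 * np.array([-1.0 + 0.5, 2.0 - 0.5])
        np.testing.assert_allclose(predict_margin(model, X), expect, atol=1e-15)

    def test_feature_count_mismatch_rejected(self):
        model = GBDTModel(config=TrainConfig(), base_margin=0.0, n_features=3)
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((2, 2)))


class TestModelSelection:
    def test_single_candidate_returned(self):
        X, y = toy_data()
        best, table = grid_search_cv(X, y, {"max_depth": [2]}, folds=3, seed=0)
        assert best.max_depth == 2 and len(table) == 1

    def test_fixed_seed_deterministic(self):
        X, y = toy_data()
        grid = {"max_depth": [1, 2], "n_estimators": [10]}
        b1, t1 = grid_search_cv(X, y, grid, seed=7)
        b2, t2 = grid_search_cv(X, y, grid, seed=7)
        assert b1 == b2
        assert [r["mean_f1_macro"] for r in t1] == [r["mean_f1_macro"] for r in t2]

    def test_xor_needs_interaction_depth(self):
        rng = np.random.default_rng(5)
        X = rng.random((400, 2))
        y = ((X[:, 0] > 0.5) ^ (X[:, 1] > 0.5)).astype(int)
        best, _ = grid_search_cv(
            X, y, {"max_depth": [1, 3], "n_estimators": [30]}, folds=3, seed=0
        )
        assert best.max_depth == 3

    def test_stratified_folds_preserve_class_balance(self):
        y = np.array([0] * 90 + [1] * 9)
        for train, test in stratified_kfold(y, 3, seed=0):
            assert y[test].sum() == 3

    def test_fold_with_single_class_rejected(self):
        with pytest.raises(ValueError):
            list(stratified_kfold(np.array([0] * 10 + [1]), 3))


class TestEvaluateClassifier:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        out = evaluate_classifier(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert out["auc"] == 1.0 and out["accuracy"] == 1.0 and out["f1_macro"] == 1.0

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        out = evaluate_classifier(y, rng.random(10_000))
        assert abs(out["auc"] - 0.5) < 0.02

    def test_tiny_hand_example(self):
        # scores: y=1 samples at 0.9, 0.4; y=0 at 0.6, 0.2
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.6, 0.2])
        out = evaluate_classifier(y, s)
        # Mann-Whitney: pairs won = (0.9>0.6)+(0.9>0.2)+(0.4>0.2) = 3 of 4
        assert out["auc"] == pytest.approx(0.75)
        # threshold 0.5: predictions (1, 0, 1, 0) -> TP=1 FP=1 FN=1 TN=1
        assert out["accuracy"] == pytest.approx(0.5)
        assert out["f1_class1"] == pytest.approx(0.5)

    def test_matches_sklearn_crosscheck(self):
        from sklearn.metrics import f1_score, roc_auc_score

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 500)
        s = np.clip(y * 0.3 + rng.random(500) * 0.7, 0, 1)
        out = evaluate_classifier(y, s)
        assert out["auc"] == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert out["f1_macro"] == pytest.approx(
            f1_score(y, (s >= 0.5).astype(int), average="macro"), abs=1e-12
        )

    def test_single_class_auc_undefined(self):
        assert np.isnan(auc_rank(np.ones(4), np.random.default_rng(0).random(4)))


class TestAgainstXGBoost:
    def test_predictions_close_to_xgboost(self):
        """Same hyperparameters, same data: margins should closely track the
        reference gradient-boosting implementation."""
        import xgboost as xgb

        X, y = toy_data(n=500, seed=2)
        cfg = TrainConfig(n_estimators=30, max_depth=3, learning_rate=0.3,
                          reg_lambda=1.0, min_child_weight=1.0)
        ours = fit_gbdt(X, y, cfg)
        ref = xgb.XGBClassifier(
            n_estimators=30, max_depth=3, learning_rate=0.3, reg_lambda=1.0,
            min_child_weight=1.0, base_score=0.5, tree_method="exact",
        )
        ref.fit(X, y)
        ours_p = predict_proba(ours, X)
        ref_p = ref.predict_proba(X)[:, 1]
        # same labels almost everywhere and correlated probabilities
        agree = np.mean((ours_p >= 0.5) == (ref_p >= 0.5))
        assert agree > 0.97
        assert np.corrcoef(ours_p, ref_p)[0, 1] > 0.98


class TestMakePairLabels:
    def test_identical_layers_all_synergy(self, rng):
        a = rng.normal(size=100)
        labels, keep, dropped = make_pair_labels(a, a.copy())
        assert np.all(labels == 1)

    def test_negated_layers_all_tradeoff(self, rng):
        a = rng.normal(size=101)
        labels, _, _ = make_pair_labels(a, -a)
        assert np.all(labels == 0)

    def test_independent_layers_balanced(self):
        rng = np.random.default_rng(0)
        labels, _, _ = make_pair_labels(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(labels.mean() - 0.5) < 0.02

    def test_constant_layer_rejected(self):
        with pytest.raises(ValueError):
            make_pair_labels(np.ones(10), np.arange(10.0))


def test_model_json_roundtrip():
    X, y = toy_data()
    model = fit_gbdt(X, y, TrainConfig(n_estimators=5))
    restored = GBDTModel.from_json(model.to_json())
    np.testing.assert_array_equal(predict_margin(model, X), predict_margin(restored, X))
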