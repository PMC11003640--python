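"""Classifier algebra: weighted trees, boosting loop invariants, vote
aggregation, bagging/stacking behavior, baselines, grid search."""

import math

import numpy as np
import pytest

from conftest import make_xy
from ecgkit.ensemble import (
    DecisionTree,
    LinearSVM,
    LogisticRegression,
    bagging_fit,
    bagging_predict,
    boost_coefficient,
    boost_fit,
    boost_predict,
    classical_fits,
    fit_tree,
    grid_search_cv,
    stacking_fit,
    stacking_predict,
    stratified_kfold,
)
from ecgkit.errors import DataError, FitError, ParameterError


class TestDecisionTree:
    def test_single_split_separates_groups(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        tree = fit_tree(X, y, max_depth=1)
        assert 1.0 < tree.root.threshold < 10.0
        assert np.mean(tree.predict(X) == y) == 1.0

    def test_pure_node_is_single_leaf(self):
        X = np.array([[0.0], [5.0], [9.0]])
        y = np.array(["a", "a", "a"], dtype=object)
        tree = fit_tree(X, y)
        assert tree.root.is_leaf
        assert list(tree.predict(X)) == ["a"] * 3

    def test_weights_steer_the_split(self):
        # one heavily weighted 'b' row among 'a's wins its region
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["a", "a", "a", "b"], dtype=object)
        w = np.array([0.01, 0.01, 0.01, 0.97])
        tree = fit_tree(X, y, sample_weight=w, max_depth=1)
        assert tree.predict(np.array([[3.0]]))[0] == "b"

    def test_empty_dataset_raises(self):
        with pytest.raises(FitError):
            fit_tree(np.empty((0, 2)), np.array([]))

    def test_near_duplicate_values_terminate(self):
        # adjacent floats: midpoint rounding must not create empty children
        x0 = 0.725
        X = np.array([[x0], [np.nextafter(x0, 1)], [np.nextafter(x0, 2)], [1.0]])
        y = np.array(["a", "b", "a", "b"], dtype=object)
        tree = fit_tree(X, y)  # must not recurse forever
        assert tree.root is not None


class TestBoostCoefficient:
    def test_half_error_two_classes_is_zero(self):
        assert boost_coefficient(0.5, 2) == pytest.approx(0.0)

    def test_printed_formula_three_classes(self):
        assert boost_coefficient(0.25, 3) == pytest.approx(math.log(3) + math.log(2))

    def test_positive_iff_better_than_chance(self):
        for K in (2, 3, 4):
            chance = (K - 1) / K
            assert boost_coefficient(chance - 1e-6, K) > 0
            assert boost_coefficient(chance + 1e-6, K) < 0

    def test_two_class_reduction(self):
        for e in (0.1, 0.25, 0.4):
            assert boost_coefficient(e, 2) == pytest.approx(math.log((1 - e) / e))


class TestBoostFit:
    def test_weights_positive_and_normalized_every_round(self):
        X, y = make_xy(0, n=150, n_classes=3, spread=2.0)
        model = boost_fit(X, y, M=10, max_depth=2)
        assert model.weight_history  # at least one completed round
        for W in model.weight_history:
            assert np.all(W > 0)
            assert abs(W.sum() - 1.0) < 1e-12

    def test_single_round_equals_base_tree(self):
        X, y = make_xy(1, n=80)
        model = boost_fit(X, y, M=1, learning_rate=0.7, max_depth=3, min_leaf=1)
        tree = fit_tree(X, y, max_depth=3, min_leaf=1)
        assert np.array_equal(boost_predict(model, X), tree.predict(X))

    def test_separable_data_reaches_zero_training_error(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-4, 0.3, (40, 2)), rng.normal(4, 0.3, (40, 2))])
        y = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        model = boost_fit(X, y, M=10, max_depth=2)
        assert np.mean(boost_predict(model, X) == y) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(FitError):
            boost_fit(np.zeros((5, 2)), np.array(["a"] * 5))

    def test_vote_aggregation_matches_brute_force(self):
        # independent oracle: tabulate scores per class explicitly
        rng = np.random.default_rng(3)
        n_cases = 0
        while n_cases < 1000:
            K = int(rng.integers(2, 5))
            X, y = make_xy(int(rng.integers(1_000_000)), n=120, n_classes=K, spread=2.5)
            model = boost_fit(X, y, M=5, max_depth=2)
            Xq, _ = make_xy(int(rng.integers(1_000_000)), n=50, n_classes=K, spread=2.5)
            got = boost_predict(model, Xq)
            for i, row in enumerate(Xq):
                scores = {c: 0.0 for c in model.classes}
                for tree, a in zip(model.learners, model.coefficients):
                    scores[tree.predict(row[None, :])[0]] += a
                top = max(scores.values())
                winners = [c for c in model.classes if scores[c] == top]
                assert got[i] == winners[0]  # earliest class on ties
                n_cases += 1

    def test_agreement_with_reference_adaboost(self, pvc_table):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        from ecgkit.evaluate import split_70_30

        agree = []
        for seed in range(1, 6):
            from ecgkit.evaluate import default_synth_config
            from ecgkit.features import build_feature_table
            from ecgkit.synth_ecg import synthesize

            record, ann, _ = synthesize(default_synth_config("PVC", seed))
            table = build_feature_table(record, ann, "PVC", lead="MLII")["MLII"]
            train, test = split_70_30(table, seed)
            ours = boost_fit(train.X, train.y, M=10, learning_rate=1.0, max_depth=6, min_leaf=3)
            ref = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=6, min_samples_leaf=3, random_state=0),
                n_estimators=10,
                learning_rate=1.0,
                random_state=0,
            ).fit(train.X, train.y)
            agree.append(np.mean(boost_predict(ours, test.X) == ref.predict(test.X)))
        assert np.mean(agree) >= 0.95


class TestBagging:
    def test_deterministic(self):
        X, y = make_xy(4, n=100)
        m1 = bagging_fit(X, y, n_estimators=5, seed=7)
        m2 = bagging_fit(X, y, n_estimators=5, seed=7)
        assert np.array_equal(bagging_predict(m1, X), bagging_predict(m2, X))

    def test_single_member_equals_resampled_tree(self):
        X, y = make_xy(5, n=60)
        model = bagging_fit(X, y, n_estimators=1, seed=3)
        assert np.array_equal(bagging_predict(model, X), model.learners[0].predict(X))

    def test_not_much_worse_than_single_tree(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(-3, 0.5, (50, 2)), rng.normal(3, 0.5, (50, 2))])
        y = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        single = np.mean(fit_tree(X, y).predict(X) == y)
        bag = bagging_fit(X, y, n_estimators=10, seed=0)
        assert np.mean(bagging_predict(bag, X) == y) >= single - 0.05

    def test_invalid_max_samples(self):
        X, y = make_xy(7, n=30)
        with pytest.raises(ParameterError):
            bagging_fit(X, y, max_samples=0)
        with pytest.raises(ParameterError):
            bagging_fit(X, y, max_samples=31)


class TestStacking:
    def test_meta_feature_width(self):
        X, y = make_xy(8, n=90, n_classes=3, spread=2.0)
        model = stacking_fit(X, y, folds=3)
        assert len(model.base_models) == 3
        # meta tree consumes n_bases * K probability columns
        proba_cols = len(model.base_models) * len(model.classes)
        deep = [model.meta.root]
        seen = set()
        while deep:
            node = deep.pop()
            if not node.is_leaf:
                seen.add(node.feature)
                deep += [node.left, node.right]
        assert all(f < proba_cols for f in seen)

    def test_perfect_identical_bases_give_perfect_stack(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(-4, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))])
        y = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        model = stacking_fit(
            X, y, base_specs=[lambda: DecisionTree(max_depth=2)] * 2, folds=3
        )
        assert np.mean(stacking_predict(model, X) == y) == 1.0

    def test_close_to_best_base(self, pvc_table):
        from ecgkit.evaluate import split_70_30

        train, test = split_70_30(pvc_table, 1)
        stack = stacking_fit(train.X, train.y, seed=1)
        stack_acc = np.mean(stacking_predict(stack, test.X) == test.y)
        base_accs = []
        for m in classical_fits(train.X, train.y, seed=1).values():
            base_accs.append(np.mean(m.predict(test.X) == test.y))
        assert stack_acc >= max(base_accs) - 0.1

    def test_too_few_folds_or_bases(self):
        X, y = make_xy(10, n=40)
        with pytest.raises(ParameterError):
            stacking_fit(X, y, folds=1)
        with pytest.raises(ParameterError):
            stacking_fit(X, y, base_specs=[lambda: DecisionTree()], folds=3)


class TestClassicalModels:
    def test_all_reach_perfect_on_separable(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(-5, 0.4, (40, 2)), rng.normal(5, 0.4, (40, 2))])
        y = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        for name, model in classical_fits(X, y, seed=0).items():
            assert np.mean(model.predict(X) == y) == 1.0, name

    def test_logistic_intercept_near_zero_on_symmetric_data(self):
        # exactly mirror-symmetric overlapping classes: x -> -x swaps labels
        rng = np.random.default_rng(12)
        half = rng.normal(-1.0, 1.5, (200, 2))
        X = np.vstack([half, -half])
        y = np.array(["a"] * 200 + ["b"] * 200, dtype=object)
        lr = LogisticRegression().fit(X, y)
        assert np.all(np.abs(lr.intercept_) < 0.05)

    def test_single_class_raises(self):
        X = np.zeros((10, 2))
        y = np.array(["a"] * 10)
        with pytest.raises(DataError):
            LogisticRegression().fit(X, y)
        with pytest.raises(DataError):
            LinearSVM().fit(X, y)

    def test_nonfinite_features_raise(self):
        X, y = make_xy(13, n=20)
        X[0, 0] = np.nan
        with pytest.raises(DataError):
            LogisticRegression().fit(X, y)


class TestGridSearch:
    def test_single_combination_is_best(self):
        X, y = make_xy(14, n=80)
        result = grid_search_cv(X, y, {"M": [3]}, folds=3, seed=0)
        assert result.best == {"M": 3}

    def test_fold_accounting(self):
        X, y = make_xy(15, n=100)
        folds = 4
        result = grid_search_cv(X, y, {"M": [1, 10]}, folds=folds, seed=0)
        for accs, mean in zip(result.fold_accuracy, result.mean_accuracy):
            assert len(accs) == folds
            assert mean == pytest.approx(np.mean(accs))

    def test_degenerate_combination_not_selected(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(-3, 0.5, (60, 2)), rng.normal(3, 0.5, (60, 2))])
        y = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
        # max_depth=0 forces a single-leaf (majority) tree: near-chance here
        result = grid_search_cv(X, y, {"M": [1], "max_depth": [0, 3]}, folds=3, seed=0)
        assert result.best["max_depth"] == 3

    def test_stratified_folds_cover_everything(self):
        _, y = make_xy(17, n=97, n_classes=3)
        splits = stratified_kfold(y, 5, seed=0)
        all_test = np.concatenate([te for _, te in splits])
        assert sorted(all_test) == list(range(len(y)))

    def test_empty_grid_rejected(self):
        X, y = make_xy(18, n=30)
        with pytest.raises(ParameterError):
            grid_search_cv(X, y, {}, folds=3)
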