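"""Metrics, ridge logistic regression and the cross-validation harness."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from molconnect.curation import LabelledDataset
from molconnect.mlbench import (
    ConfusionCounts,
    RidgeLogistic,
    classifier_bakeoff,
    cross_validate,
    default_classifiers,
    metrics,
    per_descriptor_accuracy,
    ridge_logistic_fit,
)
from molconnect.synthetic import gen_confusion_tables

from conftest import planted_dataset


class TestMetrics:
    def test_worked_example(self):
        acc, prec = metrics(ConfusionCounts(TP=8, TN=7, FP=2, FN=3))
        assert acc == 75.0
        assert prec == 80.0

    def test_all_correct(self):
        acc, prec = metrics(ConfusionCounts(10, 10, 0, 0))
        assert (acc, prec) == (100.0, 100.0)

    def test_precision_not_applicable_without_positive_predictions(self):
        acc, prec = metrics(ConfusionCounts(0, 5, 0, 5))
        assert prec is None and acc == 50.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 2)

    def test_random_tables_match_hand_formulas(self):
        for c in gen_confusion_tables(20, seed=3):
            acc, prec = metrics(c)
            assert acc == pytest.approx(100 * (c.TP + c.TN) / c.total)
            if c.TP + c.FP > 0:
                assert prec == pytest.approx(100 * c.TP / (c.TP + c.FP))
            else:
                assert prec is None


class TestRidgeLogistic:
    def test_heavy_penalty_shrinks_to_class_log_odds(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((90, 3))
        y = np.array([1] * 60 + [-1] * 30)
        coef, intercept = ridge_logistic_fit(x, y, lam=1e8)
        assert np.abs(coef).max() < 1e-3
        assert intercept == pytest.approx(np.log(60 / 30), abs=1e-2)

    def test_monotone_probability_on_separable_1d(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([-1, -1, 1, 1])
        model = RidgeLogistic(lam=1e-8).fit(x, y)
        grid = np.linspace(-1, 4, 11)[:, None]
        assert (np.diff(model.decision_function(grid)) > 0).all()
        probs = model.predict_proba(grid)[:, 1]
        assert (np.diff(probs) >= 0).all()  # saturates to 1 in float

    @pytest.mark.parametrize("lam", [1e-3, 0.1, 1.0])
    def test_matches_general_purpose_optimizer(self, lam):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((60, 4))
        y = np.where(x[:, 0] + 0.5 * rng.standard_normal(60) > 0, 1, -1)
        y01 = (y == 1).astype(float)
        xa = np.hstack([np.ones((60, 1)), x])

        def objective(b):
            z = xa @ b
            return float(np.sum(np.logaddexp(0, z) - y01 * z)
                         + lam * b[1:] @ b[1:])

        oracle = minimize(objective, np.zeros(5), method="BFGS",
                          options={"gtol": 1e-10, "maxiter": 2000})
        coef, intercept = ridge_logistic_fit(x, y, lam=lam)
        assert np.allclose(coef, oracle.x[1:], atol=1e-4)
        assert intercept == pytest.approx(oracle.x[0], abs=1e-4)

    def test_decision_boundary_invariant_to_feature_rescaling_unpenalised(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((50, 3))
        y = np.where(x @ np.array([1.0, -1.0, 0.5])
                     + rng.standard_normal(50) > 0, 1, -1)
        scaled = x * np.array([10.0, 0.1, 3.0])
        a = RidgeLogistic(lam=0.0).fit(x, y)
        b = RidgeLogistic(lam=0.0).fit(scaled, y)
        assert (a.predict(x) == b.predict(scaled)).all()

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            RidgeLogistic(lam=-1.0).fit(np.zeros((4, 1)),
                                        np.array([1, -1, 1, -1]))


class TestCrossValidate:
    def test_each_instance_tested_once_per_repeat(self):
        d = planted_dataset(n=60, seed=1)
        res = cross_validate(RidgeLogistic(), d, repeats=3, folds=5, seed=0)
        per_repeat = res.folds
        totals = [c.total for c in res.confusion]
        assert len(totals) == 3 * 5
        for r in range(3):
            assert sum(totals[r * 5:(r + 1) * 5]) == 60

    def test_stratification_within_one_instance(self):
        d = planted_dataset(n=80, seed=2)
        from sklearn.model_selection import StratifiedKFold
        pos_rate = (d.y == 1).mean()
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, test in skf.split(d.X, d.y):
            fold_pos = (d.y[test] == 1).sum()
            expect = pos_rate * len(test)
            assert abs(fold_pos - expect) <= 1

    def test_same_seed_identical_result(self):
        d = planted_dataset(n=60, seed=3)
        a = cross_validate(RidgeLogistic(), d, repeats=2, folds=5, seed=4)
        b = cross_validate(RidgeLogistic(), d, repeats=2, folds=5, seed=4)
        assert a.confusion == b.confusion
        assert a.mean_accuracy == b.mean_accuracy

    def test_folds_reduced_for_tiny_class_with_warning(self):
        d = planted_dataset(n=40, seed=4)
        d.y[:] = -1
        d.y[:4] = 1
        with pytest.warns(UserWarning, match="reducing"):
            res = cross_validate(RidgeLogistic(), d, repeats=1, folds=10,
                                 seed=0)
        assert res.folds == 4


class TestBakeoff:
    def test_ranking_is_permutation_with_name_tiebreak(self):
        d = planted_dataset(n=60, p=4, seed=5)
        menu = [("b_tree", __import__("sklearn.tree", fromlist=["x"])
                 .DecisionTreeClassifier(random_state=0)),
                ("a_tree", __import__("sklearn.tree", fromlist=["x"])
                 .DecisionTreeClassifier(random_state=0))]
        ranked = classifier_bakeoff(d, menu, seed=0, repeats=1, folds=5)
        assert [r.classifier for r in ranked] == ["a_tree", "b_tree"]
        assert ranked[0].mean_accuracy == ranked[1].mean_accuracy

    def test_empty_menu_raises(self):
        d = planted_dataset()
        with pytest.raises(ValueError):
            classifier_bakeoff(d, [], seed=0)

    def test_null_data_near_chance_for_all_classifiers(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(rng.standard_normal((300, 5)),
                         columns=list("abcde"))
        y = np.array([1, -1] * 150)
        d = LabelledDataset(x, y, "hia")
        ranked = classifier_bakeoff(d, default_classifiers(0, rf_trees=30),
                                    seed=1, repeats=1, folds=5)
        for r in ranked:
            assert abs(r.mean_accuracy - 50.0) <= 7.0, r.classifier

    def test_ridge_logistic_ranks_high_on_planted_linear_signal(self):
        top2 = 0
        runs = 6
        for seed in range(runs):
            d = planted_dataset(n=150, p=8, n_informative=3, effect=1.5,
                                seed=seed + 10)
            ranked = classifier_bakeoff(
                d, default_classifiers(seed, rf_trees=30), seed=seed,
                repeats=1, folds=5)
            names = [r.classifier for r in ranked[:2]]
            top2 += "logistic(ridge)" in names
        assert top2 >= runs - 2


class TestPerDescriptor:
    def test_combined_beats_best_single_on_additive_signal(self):
        d = planted_dataset(n=200, p=5, n_informative=3, effect=1.8, seed=20)
        profile = per_descriptor_accuracy(d, seed=0, repeats=2, folds=5)
        assert profile["combined"] >= max(profile["individual"].values())

    def test_noise_column_near_chance(self):
        d = planted_dataset(n=200, p=4, n_informative=1, effect=2.0, seed=21)
        bal = d.y.mean()
        profile = per_descriptor_accuracy(d, seed=0, repeats=2, folds=5)
        chance = 50 + abs(bal) * 50
        assert profile["individual"]["d3"] <= chance + 7

    def test_duplicated_column_identical_accuracy(self):
        d = planted_dataset(n=100, p=3, n_informative=1, effect=2.0, seed=22)
        d.X["dup"] = d.X["d0"]
        profile = per_descriptor_accuracy(d, seed=0, repeats=1, folds=5)
        assert profile["individual"]["d0"] == profile["individual"]["dup"]
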