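"""NIPALS PLS-DA, VIP scoring and the label-permutation test."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from molconnect.plsda import (
    PLSDA,
    autoscale,
    fit_plsda,
    permutation_test,
    select_vip,
    vip_scores,
)


def labelled(n=40, p=5, seed=0, informative=0, effect=2.0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    y = np.where(np.arange(n) % 2 == 0, 1, -1)
    rng.shuffle(y)
    if informative:
        x[:, :informative] += effect * (y == 1)[:, None]
    frame = pd.DataFrame(x, columns=[f"d{i}" for i in range(p)])
    return frame, y


class TestAutoscale:
    def test_columns_centred_and_unit_variance(self):
        x = np.random.default_rng(0).gamma(2.0, size=(30, 4))
        xs, mean, sd = autoscale(x)
        assert np.allclose(xs.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(xs.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_hand_example_sample_sd(self):
        xs, mean, sd = autoscale(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(xs.ravel(), [-1.0, 0.0, 1.0])
        assert sd[0] == 1.0

    def test_stored_transform_invertible(self):
        x = np.random.default_rng(1).standard_normal((20, 3)) * 5 + 2
        xs, mean, sd = autoscale(x)
        assert np.allclose(xs * sd + mean, x, atol=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError):
            autoscale(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestFit:
    def test_self_predictive_limit(self):
        x, y = labelled(n=40, p=4, seed=2)
        x["copy_of_y"] = (y == 1).astype(float)
        model = fit_plsda(x, y)
        assert model.r2y_ > 0.99

    def test_random_x_gives_nonpositive_q2_in_expectation(self):
        q2 = []
        for seed in range(20):
            x, y = labelled(n=100, p=20, seed=seed)
            q2.append(fit_plsda(x, y, A_max=2).q2_)
        assert np.mean(q2) < 0.05

    def test_single_informative_descriptor_dominates_weights(self):
        x, y = labelled(n=60, p=8, seed=3, informative=1, effect=2.0)
        model = fit_plsda(x, y)
        w1 = np.abs(model.x_weights_[:, 0])
        assert w1[0] == w1.max()
        assert vip_scores(model).idxmax() == "d0"

    def test_scores_mutually_orthogonal(self):
        x, y = labelled(n=60, p=10, seed=4, informative=3, effect=1.0)
        model = PLSDA(n_components=3).fit(x, y)
        t = model.x_scores_
        gram = t.T @ t
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_deflated_residual_orthogonal_to_scores(self):
        x, y = labelled(n=50, p=6, seed=5, informative=2)
        model = PLSDA(n_components=2).fit(x, y)
        xs = (x.to_numpy() - model.x_mean_) / model.x_std_
        residual = xs - model.x_scores_ @ model.x_loadings_.T
        assert np.abs(model.x_scores_.T @ residual).max() < 1e-8

    def test_component1_matches_sklearn_pls(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            x, y = labelled(n=20, p=5, seed=seed, informative=2)
            ours = PLSDA(n_components=1).fit(x, y)
            y01 = (y == 1).astype(float)
            ref = PLSRegression(n_components=1, scale=True).fit(
                x.to_numpy(), y01)
            w_ref = ref.x_weights_[:, 0]
            w_our = ours.x_weights_[:, 0]
            sign = np.sign(w_ref @ w_our)
            assert np.allclose(w_our, sign * w_ref, atol=1e-6)

    def test_too_few_samples_raises(self):
        x, y = labelled(n=8, p=3)
        with pytest.raises(ValueError):
            fit_plsda(x, y)

    def test_single_class_raises(self):
        x, _ = labelled(n=20, p=3)
        with pytest.raises(ValueError):
            fit_plsda(x, np.ones(20, dtype=int))

    def test_invalid_a_max_raises(self):
        x, y = labelled()
        with pytest.raises(ValueError):
            fit_plsda(x, y, A_max=0)


class TestVIP:
    def test_sum_of_squares_equals_p(self, small_study):
        d = small_study.endpoint_a
        model = fit_plsda(d.X, d.y)
        assert float((model.vip_ ** 2).sum()) == pytest.approx(
            d.X.shape[1], abs=1e-6)

    def test_all_equal_weights_give_unit_vip(self):
        y = np.where(np.arange(12) % 2 == 0, 1, -1)
        x = pd.DataFrame(
            np.repeat((y == 1).astype(float)[:, None], 3, axis=1)
            + 0.0, columns=list("abc"))
        x += np.random.default_rng(0).standard_normal((12, 1)) * 1e-6
        model = PLSDA(n_components=1).fit(x, y)
        assert np.allclose(model.vip_, 1.0, atol=1e-6)

    def test_single_descriptor_vip_is_one(self):
        x, y = labelled(n=30, p=1, informative=1)
        model = fit_plsda(x, y)
        assert model.vip_[0] == pytest.approx(1.0, abs=1e-9)

    def test_selection_sorted_and_cutoff(self):
        x, y = labelled(n=80, p=10, seed=7, informative=2, effect=2.0)
        model = fit_plsda(x, y)
        selected = select_vip(model, cutoff=1.0)
        vip = vip_scores(model)
        assert selected == sorted(selected, key=lambda n: (-vip[n], n))
        assert all(vip[n] >= 1.0 for n in selected)
        assert select_vip(model, cutoff=vip.max() + 1) == []

    def test_selection_invariant_to_column_order(self):
        x, y = labelled(n=80, p=8, seed=8, informative=2, effect=1.5)
        shuffled = x[list(np.random.default_rng(1).permutation(x.columns))]
        sel_a = set(select_vip(fit_plsda(x, y)))
        sel_b = set(select_vip(fit_plsda(shuffled, y)))
        assert sel_a == sel_b


class TestPermutation:
    def test_min_p_on_separable_data(self):
        x, y = labelled(n=40, p=4, seed=9)
        x["sep"] = (y == 1).astype(float)
        result = permutation_test(x, y, n_perm=199, seed=1)
        assert result["p_value"] == pytest.approx(1 / 200)

    def test_same_seed_reproducible(self):
        x, y = labelled(n=40, p=6, seed=10, informative=1)
        p1 = permutation_test(x, y, n_perm=99, seed=5)["p_value"]
        p2 = permutation_test(x, y, n_perm=99, seed=5)["p_value"]
        assert p1 == p2

    def test_too_few_permutations_raises(self):
        x, y = labelled()
        with pytest.raises(ValueError):
            permutation_test(x, y, n_perm=50)

    def test_q2_statistic_detects_planted_signal(self, small_study):
        d = small_study.endpoint_a
        result = permutation_test(d.X, d.y, n_perm=99, seed=2,
                                  statistic="q2")
        assert result["p_value"] <= 0.05


class TestClassifierInterface:
    def test_predicts_planted_labels_above_chance(self, small_study):
        d = small_study.endpoint_a
        model = fit_plsda(d.X, d.y)
        acc = (model.predict(d.X) == d.y).mean()
        assert acc > 0.7

    def test_get_set_params_roundtrip(self):
        model = PLSDA(max_components=4)
        params = model.get_params()
        assert params["max_components"] == 4
        model.set_params(q2_tol=0.05)
        assert model.q2_tol == 0.05
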