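"""Attention mechanism, loss functions, gradients and training behavior of
the multiple-instance regressor."""

import copy

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import histomark as hm
from histomark import amil
from histomark.amil import (
    TrainConfig,
    attention_pool,
    attention_scores,
    balanced_mse,
    cox_loss,
    forward,
    init_params,
    sample_weights,
    small_cohort_config,
)

from oracles import attention_eq1, breslow_negloglik


class TestAttention:
    def test_singleton_bag_gets_full_weight(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(1, 16))
        a = attention_scores(h, rng.normal(size=(8, 16)), rng.normal(size=8))
        np.testing.assert_allclose(a, [1.0])

    def test_identical_patches_share_weight_equally(self):
        rng = np.random.default_rng(1)
        h = np.tile(rng.normal(size=16), (4, 1))
        a = attention_scores(h, rng.normal(size=(8, 16)), rng.normal(size=8))
        np.testing.assert_allclose(a, 0.25)

    def test_matches_scalar_reference_evaluation(self):
        rng = np.random.default_rng(2)
        h = rng.normal(size=(3, 5))
        V = rng.normal(size=(4, 5))
        w = rng.normal(size=4)
        np.testing.assert_allclose(
            attention_scores(h, V, w), attention_eq1(h, V, w), atol=1e-6
        )

    def test_weights_sum_to_one_and_positive(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            K = rng.integers(1, 30)
            a = attention_scores(
                rng.normal(size=(K, 8)) * 3, rng.normal(size=(6, 8)), rng.normal(size=6)
            )
            assert abs(a.sum() - 1.0) < 1e-9
            assert (a > 0).all()

    def test_pool_selection_mean_and_permutation(self):
        rng = np.random.default_rng(4)
        h = rng.normal(size=(3, 6))
        np.testing.assert_allclose(attention_pool(h, np.array([1.0, 0, 0])), h[0])
        np.testing.assert_allclose(
            attention_pool(h, np.full(3, 1 / 3)), h.mean(axis=0)
        )
        perm = [2, 0, 1]
        a = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(
            attention_pool(h[perm], a[perm]), attention_pool(h, a)
        )
        with pytest.raises(ValueError):
            attention_pool(h, np.array([0.5, 0.5]))


class TestForward:
    def test_inference_deterministic_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        cfg = TrainConfig(embed_dim=16, attn_dim=8, seed=0)
        p = init_params(6, cfg, "sigmoid")
        bag = rng.normal(size=(20, 6))
        y1 = forward(bag, p)
        y2 = forward(bag, p)
        y3 = forward(bag[rng.permutation(20)], p)
        assert y1 == y2
        assert abs(y1 - y3) < 1e-6

    def test_expression_output_in_unit_interval(self):
        rng = np.random.default_rng(6)
        cfg = TrainConfig(embed_dim=16, attn_dim=8, seed=0)
        p = init_params(4, cfg, "sigmoid")
        for _ in range(10):
            y = forward(rng.normal(size=(7, 4)) * 10, p)
            assert 0.0 < y < 1.0

    def test_feature_dim_mismatch_raises(self):
        p = init_params(4, TrainConfig(embed_dim=8, attn_dim=4), "identity")
        with pytest.raises(ValueError):
            forward(np.zeros((3, 5)), p)


class TestSampleWeights:
    def test_uniform_occupancy_gives_unit_weights(self):
        t = np.linspace(0.05, 0.95, 10)
        np.testing.assert_allclose(sample_weights(t, weight_bins=10), 1.0)

    def test_two_bin_example(self):
        w = sample_weights(np.array([0.1, 0.2, 0.3, 0.9]), weight_bins=2)
        np.testing.assert_allclose(w, [2 / 3, 2 / 3, 2 / 3, 2.0])

    def test_mean_weight_is_one(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = rng.beta(0.5, 2.0, size=rng.integers(3, 50))
            assert abs(sample_weights(t).mean() - 1.0) < 1e-12
        with pytest.raises(ValueError):
            sample_weights(np.array([]))


class TestLosses:
    def test_balanced_mse_examples(self):
        y = np.array([1.0, 2.0])
        np.testing.assert_allclose(balanced_mse(y, y, np.ones(2)), 0.0)
        np.testing.assert_allclose(
            balanced_mse(np.array([1.0, 1.0]), np.array([0.0, 0.0]), np.ones(2)), 1.0
        )
        # hand evaluation with weights (2, 0) and residuals (1, 5)
        np.testing.assert_allclose(
            balanced_mse(np.array([1.0, 5.0]), np.array([0.0, 0.0]), np.array([2.0, 0.0])),
            1.0,
        )
        # unit weights reduce exactly to plain MSE
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=20), rng.normal(size=20)
        np.testing.assert_allclose(
            balanced_mse(a, b, np.ones(20)), np.mean((a - b) ** 2)
        )

    def test_cox_loss_hand_example(self):
        # risk sets {1,2,3} then {2,3}: loss = (ln 3 + ln 2) / 2
        loss = cox_loss(np.array([1.0, 2, 3]), np.array([1, 1, 0]), np.zeros(3))
        np.testing.assert_allclose(loss, (np.log(3) + np.log(2)) / 2, atol=1e-12)

    def test_cox_loss_shift_invariant_and_singleton(self):
        rng = np.random.default_rng(9)
        t, s = rng.exponential(size=10), rng.normal(size=10)
        e = (rng.uniform(size=10) < 0.7).astype(int)
        e[0] = 1
        np.testing.assert_allclose(
            cox_loss(t, e, s), cox_loss(t, e, s + 5.0), atol=1e-9
        )
        assert cox_loss(np.array([2.0]), np.array([1]), np.array([3.7])) == 0.0
        with pytest.raises(ValueError):
            cox_loss(t, np.zeros(10), s)

    def test_cox_loss_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(10)
        for n in range(2, 9):
            for _ in range(20):
                t = np.round(rng.exponential(size=n), 1) + 0.1  # force ties
                e = (rng.uniform(size=n) < 0.6).astype(int)
                if e.sum() == 0:
                    e[rng.integers(n)] = 1
                s = rng.normal(size=n)
                np.testing.assert_allclose(
                    cox_loss(t, e, s), breslow_negloglik(t, e, s), atol=1e-9
                )


class TestTraining:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(11)
        cfg = TrainConfig(dropout=0.0, embed_dim=8, attn_dim=4, seed=1)
        p = init_params(6, cfg, "sigmoid")
        xs = [rng.normal(size=(7, 6)) for _ in range(5)]
        y = rng.uniform(size=5)
        w = np.ones(5)

        def loss_of(params):
            def cb(y_lin):
                pred = expit(y_lin)
                dpred = 2.0 * w * (pred - y) / y.size
                return balanced_mse(y, pred, w), dpred * pred * (1 - pred)

            return amil._batch_forward_backward(
                xs, copy.deepcopy(params), cb, cfg, np.random.default_rng(0)
            )

        _, grads = loss_of(p)
        eps = 1e-6
        for name in p.trainable():
            val = getattr(p, name)
            flat_grad = np.atleast_1d(np.asarray(grads[name], dtype=float)).ravel()
            size = 1 if np.isscalar(val) else val.size
            for i in rng.choice(size, size=min(5, size), replace=False):
                for sign, store in ((1, "hi"), (-1, "lo")):
                    q = copy.deepcopy(p)
                    if np.isscalar(val):
                        setattr(q, name, val + sign * eps)
                    else:
                        getattr(q, name).ravel()[i] += sign * eps
                    if sign == 1:
                        hi, _ = loss_of(q)
                    else:
                        lo, _ = loss_of(q)
                num = (hi - lo) / (2 * eps)
                g = flat_grad[i]
                assert abs(num - g) <= 1e-5 * max(1.0, abs(num), abs(g))

    def test_loss_history_deterministic_and_decreasing(self, tiny_cohort):
        c = tiny_cohort
        y = c.expression.gene(c.expression.genes[0]).to_numpy()
        cfg = small_cohort_config(epochs=10, seed=3)
        _, h1 = amil.train(c.bags, targets=y, config=cfg)
        _, h2 = amil.train(c.bags, targets=y, config=cfg)
        assert h1 == h2  # bitwise identical history
        assert h1[-1] < h1[0]

    def test_survival_training_runs_and_is_deterministic(self, tiny_cohort):
        c = tiny_cohort
        t = c.clinical["os_months"].to_numpy()
        e = c.clinical["os_event"].to_numpy()
        cfg = small_cohort_config(epochs=4, loss="cox", seed=5)
        p1, h1 = amil.train(c.bags, survival=(t, e), config=cfg)
        p2, h2 = amil.train(c.bags, survival=(t, e), config=cfg)
        assert h1 == h2
        np.testing.assert_array_equal(p1.W1, p2.W1)
        with pytest.raises(ValueError):
            amil.train(c.bags, survival=(t, np.zeros_like(e)), config=cfg)

    def test_null_data_gives_no_spurious_correlation(self):
        # bags with no planted signal: held-out R compatible with zero
        cfg_c = hm.CohortConfig(n_samples=200, seed=21)
        zeros = hm.ExpressionMatrix(
            np.zeros((1, 200)), genes=["G000"],
            samples=[f"S{i:04d}" for i in range(200)],
        )
        bags, _, _ = hm.synthetic.generate_bags(zeros, hm.CohortConfig(
            n_samples=200, n_genes=1, seed=21))
        rng = np.random.default_rng(22)
        y = rng.normal(size=200)
        cfg = small_cohort_config(seed=4)
        params, _ = amil.train(bags[:160], targets=y[:160], config=cfg)
        yhat = amil.predict(bags[160:], params, inverse_transform=True)
        r = stats.pearsonr(yhat, y[160:])[0] if np.std(yhat) > 0 else 0.0
        assert abs(r) < 0.15

    def test_predict_inverse_transform_roundtrip(self, tiny_cohort):
        c = tiny_cohort
        y = c.expression.gene(c.expression.genes[0]).to_numpy()
        cfg = small_cohort_config(epochs=2, seed=6)
        params, _ = amil.train(c.bags, targets=y, config=cfg)
        raw = amil.predict(c.bags[:5], params)
        assert ((raw > 0) & (raw < 1)).all()
        inv = amil.predict(c.bags[:5], params, inverse_transform=True)
        span = params.target_max - params.target_min
        np.testing.assert_allclose((inv - params.target_min) / span, raw, atol=1e-9)
        params.target_min = params.target_max = None
        with pytest.raises(ValueError):
            amil.predict(c.bags[:5], params, inverse_transform=True)

    def test_checkpoint_roundtrip(self, tmp_path, tiny_cohort):
        c = tiny_cohort
        y = c.expression.gene(c.expression.genes[0]).to_numpy()
        params, _ = amil.train(
            c.bags, targets=y, config=small_cohort_config(epochs=2, seed=8)
        )
        params.save(tmp_path / "model")
        restored = amil.AmilParams.load(tmp_path / "model")
        np.testing.assert_array_equal(
            amil.predict(c.bags[:8], restored, inverse_transform=True),
            amil.predict(c.bags[:8], params, inverse_transform=True),
        )
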