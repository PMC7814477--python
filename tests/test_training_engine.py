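"""Losses, regularizers, BPTT gradients, optimizers, training loop."""

import math

import numpy as np
import pytest

from cogrnn import (LossSpec, MaskSet, NetworkSpec, TrainConfig,
                    PerceptualDiscrimination, PerceptualDiscriminationConfig,
                    WeightSet, apply_constraints_to_grads, default_initializer,
                    effective_weights, forward, make_structured_masks,
                    masked_bce, masked_mse, regularization_penalty,
                    total_loss, train)
from cogrnn.task import Batch
from cogrnn.training import (compute_gradients, init_optimizer_state,
                             optimizer_step)


def small_pd_task(coherences=(0.5,)):
    return PerceptualDiscrimination(PerceptualDiscriminationConfig(
        coherences=coherences, fixation_duration=100.0,
        stimulus_duration=300.0, response_duration=100.0))


class TestMaskedMSE:
    def test_perfect_outputs(self):
        y = np.ones((2, 3, 2))
        assert masked_mse(y, y, np.ones_like(y)) == 0.0

    def test_single_entry_closed_form(self):
        assert masked_mse(np.array([[3.0]]), np.array([[1.0]]),
                          np.array([[1.0]])) == pytest.approx(4.0)

    def test_all_zero_mask_returns_zero(self):
        o = np.random.default_rng(0).standard_normal((2, 4, 2))
        assert masked_mse(o, np.zeros_like(o), np.zeros_like(o)) == 0.0

    def test_matches_elementwise_loop(self, rng):
        o = rng.standard_normal((2, 5, 2))
        y = rng.standard_normal((2, 5, 2))
        w = rng.random((2, 5, 2))
        num = den = 0.0
        for b in range(2):
            for t in range(5):
                for j in range(2):
                    num += w[b, t, j] * (o[b, t, j] - y[b, t, j]) ** 2
                    den += w[b, t, j]
        assert masked_mse(o, y, w) == pytest.approx(num / den)


class TestMaskedBCE:
    def test_raw_zero_target_one_gives_ln2(self):
        loss = masked_bce(np.array([[0.0]]), np.array([[1.0]]),
                          np.array([[1.0]]))
        assert loss == pytest.approx(math.log(2.0), rel=1e-12)

    def test_all_zero_mask_returns_zero(self):
        assert masked_bce(np.ones((2, 2)), np.ones((2, 2)),
                          np.zeros((2, 2))) == 0.0

    def test_targets_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            masked_bce(np.zeros((1, 1)), np.array([[1.5]]), np.ones((1, 1)))

    def test_matches_scripted_elementwise_computation(self, rng):
        o = rng.standard_normal((2, 4, 2))
        y = rng.random((2, 4, 2))
        w = rng.random((2, 4, 2))
        num = den = 0.0
        for idx in np.ndindex(o.shape):
            p = 1.0 / (1.0 + math.exp(-o[idx]))
            p = min(max(p, 1e-7), 1 - 1e-7)
            num += w[idx] * -(y[idx] * math.log(p)
                              + (1 - y[idx]) * math.log(1 - p))
            den += w[idx]
        assert masked_bce(o, y, w) == pytest.approx(num / den, rel=1e-12)


class TestRegularizers:
    def test_default_spec_has_no_penalty(self, rng):
        spec = NetworkSpec(n_in=2, n_rec=4, n_out=2)
        w, m = default_initializer(spec, rng)
        rates = rng.random((2, 5, 4))
        assert regularization_penalty(w, m, rates, LossSpec()) == 0.0

    def test_single_weight_l2_closed_form(self):
        spec = NetworkSpec(n_in=1, n_rec=2, n_out=1)
        w = WeightSet(W_in_raw=np.zeros((2, 1)), W_rec_raw=np.zeros((2, 2)),
                      W_out_raw=np.zeros((1, 2)), b_rec=np.zeros(2),
                      b_out=np.zeros(1), x0=np.zeros(2))
        w.W_rec_raw[0, 1] = 3.0
        m = MaskSet.all_to_all(spec)
        ls = LossSpec(lambda_l2_w=1.0)
        assert regularization_penalty(w, m, np.zeros((1, 1, 2)), ls) \
            == pytest.approx(9.0)

    def test_matches_independent_norm_computation(self, rng):
        spec = NetworkSpec(n_in=2, n_rec=4, n_out=2, dales_ratio=0.75)
        w, m = default_initializer(spec, rng)
        rates = rng.random((2, 6, 4))
        ls = LossSpec(lambda_l1_w=0.3, lambda_l2_w=0.7, lambda_l2_rate=0.2)
        W_in, W_rec, W_out = effective_weights(w, m)
        expected = sum(0.3 * np.abs(W).sum() + 0.7 * (W ** 2).sum()
                       for W in (W_in, W_rec, W_out))
        expected += 0.2 * (rates ** 2).mean()
        assert regularization_penalty(w, m, rates, ls) \
            == pytest.approx(expected, rel=1e-12)

    def test_total_loss_is_additive(self, rng):
        spec = NetworkSpec(n_in=2, n_rec=3, n_out=2)
        w, m = default_initializer(spec, rng)
        o = rng.standard_normal((2, 4, 2))
        y = rng.standard_normal((2, 4, 2))
        mask = np.ones_like(o)
        rates = rng.random((2, 4, 3))
        ls = LossSpec(lambda_l2_w=0.1, lambda_l2_rate=0.1)
        assert total_loss(o, y, mask, w, m, rates, ls) == pytest.approx(
            masked_mse(o, y, mask)
            + regularization_penalty(w, m, rates, ls), rel=1e-12)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            LossSpec(lambda_l1_w=-0.1)


def finite_difference_grads(w, m, batch, spec, loss_spec, noise, eps=1e-5):
    """Central finite differences through the full forward pass."""
    fd = {}
    for name in ("W_in_raw", "W_rec_raw", "W_out_raw", "b_rec", "b_out"):
        arr = getattr(w, name)
        g = np.zeros_like(arr)
        for idx in np.ndindex(arr.shape):
            wp, wm_ = w.copy(), w.copy()
            getattr(wp, name)[idx] += eps
            getattr(wm_, name)[idx] -= eps
            lp = _loss_of(wp, m, batch, spec, loss_spec, noise)
            lm = _loss_of(wm_, m, batch, spec, loss_spec, noise)
            g[idx] = (lp - lm) / (2 * eps)
        fd[name] = g
    return fd


def _loss_of(w, m, batch, spec, loss_spec, noise):
    _, rates, outputs = forward(batch.inputs, w, m, spec, noise=noise)
    return total_loss(outputs, batch.targets, batch.mask, w, m, rates,
                      loss_spec)


def random_problem(seed, n_rec, T, dale, conn, fixed, loss_kind, regs,
                   transfer="relu"):
    rng = np.random.default_rng(seed)
    spec = NetworkSpec(n_in=2, n_rec=n_rec, n_out=2, sigma_rec=0.1,
                       transfer=transfer,
                       dales_ratio=0.7 if dale else None)
    w, m = default_initializer(spec, rng)
    if conn:
        m.conn_rec = (rng.random((n_rec, n_rec)) > 0.25).astype(float)
        m.conn_in = (rng.random((n_rec, 2)) > 0.25).astype(float)
    if fixed:
        m.train_rec = (rng.random((n_rec, n_rec)) > 0.3).astype(float)
        m.train_b_out = np.zeros(2)
    B = 2
    batch = Batch(rng.standard_normal((B, T, 2)),
                  rng.random((B, T, 2)),
                  (rng.random((B, T, 2)) > 0.3).astype(float),
                  [{} for _ in range(B)])
    noise = rng.standard_normal((B, T, n_rec))
    l1, l2, lr = (0.01, 0.02, 0.05) if regs else (0.0, 0.0, 0.0)
    ls = LossSpec(loss=loss_kind, lambda_l1_w=l1, lambda_l2_w=l2,
                  lambda_l2_rate=lr)
    return w, m, batch, spec, ls, noise


GRAD_CASES = [
    # (seed, n_rec, T, dale, conn, fixed, loss, regs, transfer)
    (0, 2, 3, False, False, False, "mean_squared_error", False, "relu"),
    (1, 3, 5, False, False, False, "mean_squared_error", True, "relu"),
    (2, 3, 5, True, False, False, "mean_squared_error", False, "relu"),
    (3, 5, 10, True, True, True, "mean_squared_error", True, "relu"),
    (4, 3, 5, False, True, False, "binary_cross_entropy", False, "tanh"),
    (5, 5, 10, True, False, True, "binary_cross_entropy", True, "sigmoid"),
    (6, 2, 10, False, False, False, "binary_cross_entropy", False, "relu"),
    (7, 5, 3, True, True, False, "mean_squared_error", False, "tanh"),
]


class TestGradients:
    def test_flat_minimum_has_zero_gradients(self):
        spec = NetworkSpec(n_in=2, n_rec=3, n_out=2, sigma_rec=0.0)
        w = WeightSet(W_in_raw=np.zeros((3, 2)), W_rec_raw=np.zeros((3, 3)),
                      W_out_raw=np.zeros((2, 3)), b_rec=np.zeros(3),
                      b_out=np.zeros(2), x0=np.zeros(3))
        m = MaskSet.all_to_all(spec)
        batch = Batch(np.zeros((1, 5, 2)), np.zeros((1, 5, 2)),
                      np.ones((1, 5, 2)), [{}])
        grads, loss, _, _ = compute_gradients(w, m, batch, spec, LossSpec(),
                                              np.zeros((1, 5, 3)))
        assert loss == 0.0
        for g in grads.values():
            assert np.all(g == 0)

    @pytest.mark.parametrize("case", GRAD_CASES, ids=lambda c: f"cfg{c[0]}")
    def test_bptt_matches_central_finite_differences(self, case):
        seed, n_rec, T, dale, conn, fixed, loss_kind, regs, tf = case
        w, m, batch, spec, ls, noise = random_problem(
            seed, n_rec, T, dale, conn, fixed, loss_kind, regs, tf)
        grads, _, _, _ = compute_gradients(w, m, batch, spec, ls, noise)
        fd = finite_difference_grads(w, m, batch, spec, ls, noise)
        for name in grads:
            denom = np.maximum.reduce([np.abs(fd[name]), np.abs(grads[name]),
                                       np.full_like(fd[name], 1e-6)])
            rel = np.abs(fd[name] - grads[name]) / denom
            assert rel.max() < 1e-4, f"{name}: max rel err {rel.max():.2e}"

    def test_forbidden_connections_get_zero_gradient(self):
        w, m, batch, spec, ls, noise = random_problem(
            3, 5, 10, True, True, True, "mean_squared_error", True)
        grads, _, _, _ = compute_gradients(w, m, batch, spec, ls, noise)
        assert np.all(grads["W_rec_raw"][m.conn_rec == 0] == 0)
        assert np.all(grads["W_in_raw"][m.conn_in == 0] == 0)


class TestConstraintApplication:
    def test_all_plastic_leaves_gradients_unchanged(self, rng):
        spec = NetworkSpec(n_in=2, n_rec=4, n_out=2)
        _, m = default_initializer(spec, rng)
        grads = {"W_in_raw": rng.standard_normal((4, 2)),
                 "W_rec_raw": rng.standard_normal((4, 4)),
                 "W_out_raw": rng.standard_normal((2, 4)),
                 "b_rec": rng.standard_normal(4),
                 "b_out": rng.standard_normal(2)}
        out = apply_constraints_to_grads(grads, m)
        for k in grads:
            assert np.array_equal(out[k], grads[k])

    def test_frozen_recurrent_zeroes_its_gradient(self, rng):
        spec = NetworkSpec(n_in=2, n_rec=4, n_out=2)
        _, m = default_initializer(spec, rng)
        m.train_rec = np.zeros((4, 4))
        grads = {"W_in_raw": np.ones((4, 2)), "W_rec_raw": np.ones((4, 4)),
                 "W_out_raw": np.ones((2, 4)), "b_rec": np.ones(4),
                 "b_out": np.ones(2)}
        out = apply_constraints_to_grads(grads, m)
        assert np.all(out["W_rec_raw"] == 0)
        assert np.all(out["W_in_raw"] == 1)

    def test_dale_fixed_ei_zeroes_exactly_cross_sign_entries(self, rng):
        spec = NetworkSpec(n_in=2, n_rec=10, n_out=2, dales_ratio=0.8)
        _, m = default_initializer(spec, rng)
        m = make_structured_masks("dale_fixed_ei", m)
        grads = {"W_in_raw": np.ones((10, 2)), "W_rec_raw": np.ones((10, 10)),
                 "W_out_raw": np.ones((2, 10)), "b_rec": np.ones(10),
                 "b_out": np.ones(2)}
        out = apply_constraints_to_grads(grads, m)
        s = m.dale_signs
        cross = (s[:, None] * s[None, :]) < 0
        assert np.all(out["W_rec_raw"][cross] == 0)
        assert np.all(out["W_rec_raw"][~cross] == 1)


class TestOptimizers:
    def _scalar_setup(self, optimizer, lr):
        cfg = TrainConfig(optimizer=optimizer, learning_rate=lr)
        params = {"p": np.array([1.0])}
        return cfg, params, init_optimizer_state(cfg, params)

    def test_sgd_single_step(self):
        cfg, params, state = self._scalar_setup("sgd", 0.1)
        _, new = optimizer_step(state, params, {"p": np.array([2.0])}, cfg)
        assert new["p"][0] == pytest.approx(0.8)

    @pytest.mark.parametrize("optimizer", ["sgd", "adam", "rmsprop"])
    def test_zero_gradient_leaves_parameters_unchanged(self, optimizer):
        cfg, params, state = self._scalar_setup(optimizer, 0.1)
        _, new = optimizer_step(state, params, {"p": np.zeros(1)}, cfg)
        assert new["p"][0] == pytest.approx(1.0)

    def test_adam_matches_scripted_reference_on_quadratic(self):
        # minimize f(p) = p^2 from p = 1 for 10 steps
        cfg, params, state = self._scalar_setup("adam", 0.1)
        p_ref, m_ref, v_ref = 1.0, 0.0, 0.0
        b1, b2, eps = 0.9, 0.999, 1e-8
        for t in range(1, 11):
            g = 2.0 * p_ref
            m_ref = b1 * m_ref + (1 - b1) * g
            v_ref = b2 * v_ref + (1 - b2) * g * g
            p_ref -= 0.1 * (m_ref / (1 - b1 ** t)) / (
                math.sqrt(v_ref / (1 - b2 ** t)) + eps)
            g_pkg = 2.0 * params["p"]
            state, params = optimizer_step(state, params, {"p": g_pkg}, cfg)
            assert params["p"][0] == pytest.approx(p_ref, abs=1e-12)

    def test_rmsprop_matches_scripted_reference(self):
        cfg, params, state = self._scalar_setup("rmsprop", 0.05)
        p_ref, v_ref = 1.0, 0.0
        for _ in range(5):
            g = 2.0 * p_ref
            v_ref = 0.9 * v_ref + 0.1 * g * g
            p_ref -= 0.05 * g / (math.sqrt(v_ref) + 1e-8)
            state, params = optimizer_step(state, params,
                                           {"p": 2.0 * params["p"]}, cfg)
            assert params["p"][0] == pytest.approx(p_ref, abs=1e-12)

    def test_global_norm_clipping(self):
        cfg = TrainConfig(optimizer="sgd", learning_rate=1.0,
                          grad_clip_norm=1.0)
        params = {"a": np.array([0.0]), "b": np.array([0.0])}
        grads = {"a": np.array([3.0]), "b": np.array([4.0])}  # norm 5
        _, new = optimizer_step(init_optimizer_state(cfg, params), params,
                                grads, cfg)
        assert new["a"][0] == pytest.approx(-0.6)
        assert new["b"][0] == pytest.approx(-0.8)


class TestTrainingLoop:
    def test_zero_iterations_returns_weights_unchanged(self, rng):
        task = small_pd_task()
        spec = NetworkSpec(n_in=2, n_rec=8, n_out=2)
        w, m = default_initializer(spec, rng)
        cfg = TrainConfig(n_iterations=0, master_seed=1)
        w2, trace = train(w, m, task, spec, LossSpec(), cfg)
        for name in ("W_in_raw", "W_rec_raw", "W_out_raw", "b_rec", "b_out"):
            assert np.array_equal(getattr(w2, name), getattr(w, name))
        assert trace.iterations == []

    def test_identical_master_seed_gives_identical_trace(self, rng):
        task = small_pd_task()
        spec = NetworkSpec(n_in=2, n_rec=8, n_out=2)
        w, m = default_initializer(spec, rng)
        cfg = TrainConfig(n_iterations=30, batch_size=8, eval_batch=16,
                          master_seed=9)
        w1, tr1 = train(w, m, task, spec, LossSpec(), cfg)
        w2, tr2 = train(w, m, task, spec, LossSpec(), cfg)
        assert tr1.loss_values == tr2.loss_values
        assert tr1.accuracy_values == tr2.accuracy_values
        assert np.array_equal(w1.W_rec_raw, w2.W_rec_raw)

    def test_dale_sign_purity_preserved_by_training(self, rng):
        task = small_pd_task()
        spec = NetworkSpec(n_in=2, n_rec=10, n_out=2, dales_ratio=0.8)
        w, m = default_initializer(spec, rng)
        signs_before = np.sign(effective_weights(w, m)[1])
        cfg = TrainConfig(n_iterations=200, batch_size=8, eval_batch=16,
                          master_seed=3)
        w2, _ = train(w, m, task, spec, LossSpec(), cfg)
        _, W_rec, W_out = effective_weights(w2, m)
        for j, s in enumerate(m.dale_signs):
            assert np.all(s * W_rec[:, j] >= 0)
            assert np.all(s * W_out[:, j] >= 0)
        # training moved the weights, so purity is not vacuous
        assert not np.array_equal(np.abs(w.W_rec_raw), np.abs(w2.W_rec_raw))
        del signs_before

    def test_frozen_entries_bit_identical_after_training(self, rng):
        task = small_pd_task()
        spec = NetworkSpec(n_in=2, n_rec=10, n_out=2, dales_ratio=0.8)
        w, m = default_initializer(spec, rng)
        m = make_structured_masks("dale_fixed_ei", m)
        cfg = TrainConfig(n_iterations=200, batch_size=8, eval_batch=16,
                          master_seed=4)
        w2, _ = train(w, m, task, spec, LossSpec(), cfg)
        frozen = m.train_rec == 0
        assert np.array_equal(w.W_rec_raw[frozen], w2.W_rec_raw[frozen])
        assert not np.array_equal(w.W_rec_raw[~frozen], w2.W_rec_raw[~frozen])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_eval_loss_trends_downward(self, seed):
        """Median eval loss over the last 10% of iterations must fall below
        the median over the first 10% (perceptual discrimination,
        default-style settings at reduced size for speed)."""
        task = small_pd_task((0.5,))
        spec = NetworkSpec(n_in=2, n_rec=20, n_out=2)
        w, m = default_initializer(spec, np.random.default_rng(seed))
        cfg = TrainConfig(n_iterations=200, eval_every=10, batch_size=32,
                          eval_batch=64, master_seed=seed)
        _, trace = train(w, m, task, spec, LossSpec(), cfg)
        losses = np.array(trace.loss_values)
        k = max(1, len(losses) // 10)
        assert np.median(losses[-k:]) < np.median(losses[:k])

    def test_mismatched_task_and_network_widths_rejected(self, rng):
        task = small_pd_task()
        spec = NetworkSpec(n_in=3, n_rec=8, n_out=2)
        w, m = default_initializer(spec, rng)
        with pytest.raises(ValueError):
            train(w, m, task, spec, LossSpec(),
                  TrainConfig(n_iterations=1, master_seed=0))
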