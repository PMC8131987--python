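"""Feedforward network: scaling, forward pass, analytic Jacobian and the
Levenberg–Marquardt training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluorstab.network import (LMState, MinMaxScaling, TrainOptions,
                               accumulate_normal_equations, flatten_params,
                               forward_pass, initialize_network, lm_step,
                               model_from_json, model_to_json, n_parameters,
                               network_jacobian, predict, scale_apply,
                               scale_fit, scale_invert, set_params,
                               train_network)


class TestScaling:
    def test_three_point_column(self):
        s = scale_fit(np.array([[0.0], [5.0], [10.0]]))
        out = scale_apply(np.array([[0.0], [5.0], [10.0]]), s)
        np.testing.assert_allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0]])
        s = scale_fit(X)
        out = scale_apply(X, s)
        np.testing.assert_array_equal(out[:, 0], [0.0, 0.0])
        # and inverts back to the constant
        np.testing.assert_allclose(scale_invert(out, s), X)

    def test_unfitted_scaling_rejected(self):
        with pytest.raises(ValueError):
            scale_apply(np.ones((2, 2)), None)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 4)) * rng.uniform(0.1, 1e4)
        s = scale_fit(X)
        back = scale_invert(scale_apply(X, s), s)
        np.testing.assert_allclose(back, X, rtol=1e-12, atol=1e-9)


class TestInitialization:
    def test_seed_reproducibility(self):
        a = initialize_network(20, 20, 20, seed=3)
        b = initialize_network(20, 20, 20, seed=3)
        np.testing.assert_array_equal(flatten_params(a), flatten_params(b))

    def test_parameter_count_default_architecture(self):
        net = initialize_network(20, 20, 20, seed=0)
        assert n_parameters(net) == 840  # (20·20+20) + (20·20+20)

    def test_degenerate_single_hidden_unit(self):
        net = initialize_network(3, 1, 2, seed=0)
        assert forward_pass(net, np.zeros((1, 3))).shape == (1, 2)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            initialize_network(0, 5, 2, seed=0)


class TestForwardPass:
    def test_zero_weights_output_bias(self):
        net = initialize_network(4, 3, 2, seed=0)
        net.W1 *= 0.0
        net.W2 *= 0.0
        net.b2 = np.array([1.5, -2.0])
        out = forward_pass(net, np.random.default_rng(0).normal(size=(5, 4)))
        np.testing.assert_allclose(out, np.tile([1.5, -2.0], (5, 1)))

    def test_zero_output_weights_input_independent(self):
        net = initialize_network(4, 3, 2, seed=1)
        net.W2 *= 0.0
        rng = np.random.default_rng(1)
        a = forward_pass(net, rng.normal(size=(1, 4)))
        b = forward_pass(net, rng.normal(size=(1, 4)))
        np.testing.assert_array_equal(a, b)

    def test_batched_equals_single_sample(self):
        net = initialize_network(6, 5, 3, seed=2)
        X = np.random.default_rng(2).normal(size=(10, 6))
        batched = forward_pass(net, X)
        singles = np.vstack([forward_pass(net, X[i:i + 1]) for i in range(10)])
        np.testing.assert_allclose(batched, singles, rtol=1e-12, atol=1e-14)

    def test_shape_mismatch_rejected(self):
        net = initialize_network(4, 3, 2, seed=0)
        with pytest.raises(ValueError):
            forward_pass(net, np.zeros((2, 5)))


def _fd_jacobian(net, X, T, eps=1e-6):
    """Central finite differences of e = (T − pred).ravel() w.r.t. params."""
    x0 = flatten_params(net)
    rows = X.shape[0] * net.n_out
    J = np.empty((rows, x0.size))
    for j in range(x0.size):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += eps
        xm[j] -= eps
        ep = (T - forward_pass(set_params(net, xp), X)).ravel()
        em = (T - forward_pass(set_params(net, xm), X)).ravel()
        J[:, j] = (ep - em) / (2 * eps)
    return J


class TestJacobian:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n_in, n_hid, n_out = rng.integers(1, 5, size=3)
        net = initialize_network(int(n_in), int(n_hid), int(n_out),
                                 seed=int(seed % 2**16))
        X = rng.uniform(-1, 1, size=(4, n_in))
        T = rng.uniform(-1, 1, size=(4, n_out))
        state = network_jacobian(net, X, T)
        J_fd = _fd_jacobian(net, X, T)
        np.testing.assert_allclose(state.J, J_fd, rtol=1e-6, atol=1e-7)

    def test_mse_gradient_identity(self):
        """∇MSE = −2·Jᵀe/N when J = ∂e/∂x with e = target − prediction...
        here checked as ∂SSE/∂x = 2·Jᵀe against finite differences."""
        rng = np.random.default_rng(8)
        net = initialize_network(3, 4, 2, seed=8)
        X = rng.uniform(-1, 1, size=(6, 3))
        T = rng.uniform(-1, 1, size=(6, 2))
        state = network_jacobian(net, X, T)
        grad_analytic = 2.0 * state.J.T @ state.e
        x0 = flatten_params(net)
        eps = 1e-6
        grad_fd = np.empty_like(x0)
        for j in range(x0.size):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += eps
            xm[j] -= eps
            sp = np.sum((T - forward_pass(set_params(net, xp), X)) ** 2)
            sm = np.sum((T - forward_pass(set_params(net, xm), X)) ** 2)
            grad_fd[j] = (sp - sm) / (2 * eps)
        np.testing.assert_allclose(grad_analytic, grad_fd, rtol=1e-6,
                                   atol=1e-8)

    def test_block_accumulation_matches_monolithic(self):
        rng = np.random.default_rng(9)
        net = initialize_network(5, 6, 4, seed=9)
        X = rng.uniform(-1, 1, size=(37, 5))
        T = rng.uniform(-1, 1, size=(37, 4))
        w = rng.uniform(0.5, 2.0, size=4)
        state = network_jacobian(net, X, T, weights=w)
        jtj, jte, sse = accumulate_normal_equations(net, X, T, weights=w,
                                                    block_size=8)
        np.testing.assert_allclose(jtj, state.J.T @ state.J, rtol=1e-10)
        np.testing.assert_allclose(jte, state.J.T @ state.e, rtol=1e-10)
        assert sse == pytest.approx(float(state.e @ state.e), rel=1e-12)


class TestLMStep:
    def linear_state(self, mu):
        """A purely linear least-squares problem disguised as an LMState."""
        rng = np.random.default_rng(4)
        A = rng.normal(size=(30, 6))
        x = rng.normal(size=6)
        t = rng.normal(size=30)
        e = t - A @ x
        return LMState(x=x, J=-A, e=e, mu=mu), A, t

    def test_small_mu_reaches_least_squares_optimum(self):
        state, A, t = self.linear_state(mu=1e-12)
        x_new = lm_step(state)
        x_opt, *_ = np.linalg.lstsq(A, t, rcond=None)
        np.testing.assert_allclose(x_new, x_opt, rtol=1e-6)

    def test_huge_mu_vanishing_step(self):
        state1, _, _ = self.linear_state(mu=1.0)
        state2, _, _ = self.linear_state(mu=1e10)
        step1 = np.linalg.norm(lm_step(state1) - state1.x)
        step2 = np.linalg.norm(lm_step(state2) - state2.x)
        assert step2 < 1e-6 * step1

    def test_zero_error_fixed_point(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(10, 3))
        x = rng.normal(size=3)
        state = LMState(x=x, J=-A, e=np.zeros(10), mu=1e-3)
        np.testing.assert_allclose(lm_step(state), x, atol=1e-12)

    def test_nonpositive_mu_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            LMState(x=np.zeros(2), J=rng.normal(size=(4, 2)),
                    e=np.zeros(4), mu=0.0)


def _toy_problem(seed=0, n=80, noise=0.02):
    """A smooth 2-in/2-out mapping the default architecture learns easily."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-2, 2, size=(n, 2))
    Y = np.column_stack([
        np.sin(X[:, 0]) + 0.5 * X[:, 1],
        np.cos(X[:, 1]) - 0.3 * X[:, 0],
    ]) * 100.0 + 500.0
    Y = Y * (1 + rng.normal(0, noise, Y.shape))
    return X, Y


class TestTraining:
    def test_training_mse_non_increasing(self):
        X, Y = _toy_problem(1)
        net = initialize_network(2, 8, 2, seed=1)
        opts = TrainOptions(max_epochs=40, goal_mse=1e-9, seed=1)
        _, hist = train_network(net, (X[:60], Y[:60]), (X[60:], Y[60:]),
                                None, opts)
        mses = np.array(hist.train_mse)
        assert np.all(np.diff(mses) <= 1e-9)

    def test_best_model_has_minimum_validation_mse(self):
        X, Y = _toy_problem(2)
        net = initialize_network(2, 8, 2, seed=2)
        opts = TrainOptions(max_epochs=30, goal_mse=1e-9, seed=2)
        best, hist = train_network(net, (X[:60], Y[:60]), (X[60:], Y[60:]),
                                   None, opts)
        from fluorstab.network import scale_apply as sa
        val_best = np.mean(((sa(Y[60:], best.output_scaling)
                             - forward_pass(best, sa(X[60:], best.input_scaling)))
                            * best.output_scaling.half_range) ** 2)
        assert val_best == pytest.approx(min(hist.val_mse), rel=1e-9)
        assert hist.val_mse[hist.best_epoch] == min(hist.val_mse)

    def test_adversarial_early_stopping_after_ten_failures(self):
        """A validation pair that training can only hurt: early stopping
        fires after exactly 10 consecutive degradations past the best."""
        X, Y = _toy_problem(3, noise=0.0)
        # validation targets orthogonal to the learnable mapping
        Xv = X[:6].copy()
        Yv = -Y[:6] + 2 * Y[:6].mean()
        net = initialize_network(2, 8, 2, seed=3)
        opts = TrainOptions(max_epochs=500, goal_mse=1e-12, seed=3)
        _, hist = train_network(net, (X, Y), (Xv, Yv), None, opts)
        assert hist.stop_reason == "validation"
        # trailing run of degradations has length exactly 10
        v = np.array(hist.val_mse)
        best = v.min()
        tail = v[hist.best_epoch + 1:]
        assert tail.size == 10
        assert np.all(tail >= best)

    def test_goal_stop_and_mu_schedule(self):
        X, Y = _toy_problem(4)
        net = initialize_network(2, 10, 2, seed=4)
        opts = TrainOptions(max_epochs=200, goal_mse=500.0, seed=4)
        _, hist = train_network(net, (X[:60], Y[:60]), (X[60:], Y[60:]),
                                (X[60:], Y[60:]), opts)
        assert hist.stop_reason == "goal"
        assert hist.train_mse[-1] <= 500.0
        mus = np.array(hist.mu)
        assert np.all((mus > 0) & (mus <= opts.mu_max))

    def test_empty_validation_rejected(self):
        X, Y = _toy_problem(5)
        net = initialize_network(2, 4, 2, seed=5)
        with pytest.raises(ValueError):
            train_network(net, (X, Y), (X[:0], Y[:0]), None, TrainOptions())


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self):
        X, Y = _toy_problem(6)
        net = initialize_network(2, 6, 2, seed=6)
        opts = TrainOptions(max_epochs=5, goal_mse=1e-9, seed=6)
        trained, hist = train_network(net, (X[:60], Y[:60]), (X[60:], Y[60:]),
                                      None, opts)
        restored = model_from_json(model_to_json(trained, hist, opts))
        np.testing.assert_allclose(predict(restored, X), predict(trained, X))
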