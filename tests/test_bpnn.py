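import numpy as np
import pytest

from lipusopt import bpnn


def random_params(topology, seed):
    return bpnn.NetworkParameters.random(topology, np.random.default_rng(seed))


def forward_loop_oracle(params, x, activation="sigmoid"):
    """Index-by-index forward pass, no linear algebra shortcuts."""
    f, _ = bpnn.ACTIVATIONS[activation]
    t = params.topology
    y = np.empty(t.n_hidden)
    for j in range(t.n_hidden):
        net = -params.thresh_hidden[j]
        for i in range(t.n_input):
            net += params.w_in_hidden[i, j] * x[i]
        y[j] = f(np.array(net))
    o = np.empty(t.n_output)
    for k in range(t.n_output):
        s = -params.thresh_out[k]
        for j in range(t.n_hidden):
            s += y[j] * params.w_hidden_out[j, k]
        o[k] = s
    return y, o


class TestForward:
    def test_all_zero_parameters(self):
        t = bpnn.NetworkTopology(3, 8, 1)
        params = bpnn.NetworkParameters(
            np.zeros((3, 8)), np.zeros((8, 1)), np.zeros(8), np.zeros(1)
        )
        y, o = bpnn.forward(params, np.zeros(3))
        assert np.all(y == 0.5)
        assert np.all(o == 0.0)

    def test_single_hidden_unit_composition(self):
        params = bpnn.NetworkParameters([[1.0]], [[2.0]], [0.0], [0.3])
        x = np.array([0.7])
        _, o = bpnn.forward(params, x)
        sig = 1 / (1 + np.exp(-0.7))
        assert o[0] == pytest.approx(sig * 2.0 - 0.3, rel=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("activation", ["sigmoid", "identity"])
    def test_matches_index_loop_oracle(self, seed, activation):
        rng = np.random.default_rng(seed)
        t = bpnn.NetworkTopology(3, 4, 2)
        params = random_params(t, seed)
        x = rng.uniform(-2, 2, 3)
        y, o = bpnn.forward(params, x, activation)
        y_ref, o_ref = forward_loop_oracle(params, x, activation)
        np.testing.assert_allclose(y, y_ref, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(o, o_ref, rtol=1e-12, atol=1e-15)

    def test_shape_mismatch_raises(self):
        params = random_params(bpnn.NetworkTopology(3, 4, 1), 0)
        with pytest.raises(ValueError, match="features"):
            bpnn.forward(params, np.zeros(5))


def per_sample_error(params, x, d, activation="sigmoid"):
    _, o = bpnn.forward(params, x, activation)
    return 0.5 * float(np.sum((d - o) ** 2))


def analytic_gradient(params, x, d, cfg):
    """Recover the per-sample gradient of E from one backprop step:
    new = old - eta * grad, so grad = (old - new) / eta."""
    new, _ = bpnn.backprop_epoch(params, x[None, :], d[None, :], cfg)
    return (params.to_vector() - new.to_vector()) / cfg.learning_rate


class TestBackpropGradients:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_central_finite_difference(self, seed):
        """Every analytic partial derivative of the per-sample error agrees
        with a central finite difference to 1e-5 relative."""
        rng = np.random.default_rng(seed)
        t = bpnn.NetworkTopology(3, 4, 2)
        params = random_params(t, seed + 100)
        x = rng.uniform(-1, 1, 3)
        d = rng.uniform(-1, 1, 2)
        cfg = bpnn.TrainingConfig(learning_rate=0.1)
        grad = analytic_gradient(params, x, d, cfg)

        vec = params.to_vector()
        h = 1e-6
        for idx in range(t.n_params):
            up, dn = vec.copy(), vec.copy()
            up[idx] += h
            dn[idx] -= h
            fd = (
                per_sample_error(bpnn.NetworkParameters.from_vector(t, up), x, d)
                - per_sample_error(bpnn.NetworkParameters.from_vector(t, dn), x, d)
            ) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_perfect_prediction_is_a_fixed_point(self):
        params = random_params(bpnn.NetworkTopology(2, 3, 1), 0)
        X = np.array([[0.1, 0.2], [0.5, -0.4]])
        _, D = bpnn.forward(params, X)
        new, mse = bpnn.backprop_epoch(params, X, D, bpnn.TrainingConfig())
        assert mse == 0.0
        np.testing.assert_array_equal(new.to_vector(), params.to_vector())

    def test_error_decreases_over_consecutive_epochs(self):
        rng = np.random.default_rng(3)
        params = random_params(bpnn.NetworkTopology(2, 4, 1), 3)
        X = rng.uniform(0, 1, (6, 2))
        D = rng.uniform(0, 1, (6, 1))
        cfg = bpnn.TrainingConfig(learning_rate=0.01)
        p1, mse1 = bpnn.backprop_epoch(params, X, D, cfg)
        _, mse2 = bpnn.backprop_epoch(p1, X, D, cfg)
        assert mse2 <= mse1

    def test_empty_batch_rejected(self):
        params = random_params(bpnn.NetworkTopology(2, 3, 1), 0)
        with pytest.raises(ValueError, match="nonempty"):
            bpnn.backprop_epoch(params, np.empty((0, 2)), np.empty((0, 1)), bpnn.TrainingConfig())


class TestTrain:
    def test_already_fit_stops_at_epoch_one(self):
        params = random_params(bpnn.NetworkTopology(2, 3, 1), 1)
        X = np.array([[0.3, 0.6]])
        _, D = bpnn.forward(params, X)
        trained, trace = bpnn.train(params, X, D, bpnn.TrainingConfig())
        assert trace.stop_reason == "error_goal"
        assert trace.epochs_run == 1
        np.testing.assert_array_equal(trained.to_vector(), params.to_vector())

    def test_huge_error_goal_stops_after_one_epoch(self):
        params = random_params(bpnn.NetworkTopology(2, 3, 1), 2)
        X = np.array([[0.3, 0.6], [0.1, 0.9]])
        D = np.array([[0.2], [0.8]])
        _, trace = bpnn.train(params, X, D, bpnn.TrainingConfig(error_goal=1e6))
        assert trace.epochs_run == 1
        assert trace.stop_reason == "error_goal"

    def test_xor_like_error_shrinks(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        D = np.array([[0.0], [1.0], [1.0], [0.0]])
        params = random_params(bpnn.NetworkTopology(2, 8, 1), 7)
        _, trace = bpnn.train(params, X, D, bpnn.TrainingConfig(max_epochs=1000))
        assert trace.mse[-1] < trace.mse[0]

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(0).uniform(0, 1, (10, 3))
        D = np.random.default_rng(1).uniform(0, 1, (10, 1))
        t = bpnn.NetworkTopology(3, 5, 1)
        cfg = bpnn.TrainingConfig(max_epochs=50)
        runs = []
        for _ in range(2):
            params = random_params(t, 42)
            trained, trace = bpnn.train(params, X, D, cfg)
            runs.append((trained.to_vector(), trace.mse))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_identity_activation_approaches_least_squares(self):
        """With a linear hidden layer the network is an (overparameterized)
        linear model, so training should approach the OLS fit."""
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (60, 3))
        y = 0.2 + X @ np.array([0.3, -0.5, 0.4]) + rng.normal(0, 0.05, 60)
        D = y[:, None]
        A = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        ols_mse = float(np.mean((y - A @ beta) ** 2))

        cfg = bpnn.TrainingConfig(
            learning_rate=0.05, max_epochs=2000, error_goal=1e-12,
            hidden_activation="identity",
        )
        params = random_params(bpnn.NetworkTopology(3, 4, 1), 5)
        trained, _ = bpnn.train(params, X, D, cfg)
        _, O = bpnn.forward(trained, X, "identity")
        net_mse = float(np.mean((y - O.ravel()) ** 2))
        assert net_mse <= 1.10 * ols_mse


class TestScaler:
    def test_endpoint_and_midpoint_mapping(self):
        s = bpnn.fit_scaler([[5.0, 8.0], [0.6, 1.2]])
        np.testing.assert_allclose(s.apply([5.0, 0.6]), [0.0, 0.0])
        np.testing.assert_allclose(s.apply([8.0, 1.2]), [1.0, 1.0])
        assert s.apply([5.0, 0.9])[1] == pytest.approx(0.5)

    def test_round_trip(self):
        s = bpnn.fit_scaler([[3.0, 9.0]])
        assert s.invert(s.apply([7.3]))[0] == pytest.approx(7.3, rel=1e-12)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bpnn.fit_scaler([[1.0, 1.0]])

    def test_constant_dimension_maps_to_half(self):
        s = bpnn.fit_scaler([[0.0, 1.0], [2.0, 2.0]], allow_degenerate=True)
        assert s.apply([0.5, 2.0])[1] == 0.5


class TestSerialization:
    def test_json_round_trip(self):
        params = random_params(bpnn.NetworkTopology(3, 8, 1), 9)
        again = bpnn.NetworkParameters.from_json(params.to_json())
        np.testing.assert_array_equal(again.to_vector(), params.to_vector())
        assert again.topology == params.topology

    def test_vector_round_trip(self):
        t = bpnn.NetworkTopology(2, 3, 2)
        params = random_params(t, 4)
        again = bpnn.NetworkParameters.from_vector(t, params.to_vector())
        np.testing.assert_array_equal(again.w_in_hidden, params.w_in_hidden)
        np.testing.assert_array_equal(again.thresh_out, params.thresh_out)
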