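"""Network primitives, hand-derived gradients vs finite differences, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emocomp import odcnn
from emocomp.odcnn import (
    ODCNNConfig,
    ODCNNModel,
    TrainingDivergedError,
    conv1d_padded,
    conv1d_valid,
    downsample,
    elu,
    elu_prime,
    mse_loss,
    upsample_zero_order,
)


class TestConvPrimitives:
    def test_valid_identity_kernel(self):
        assert np.allclose(conv1d_valid([1, 2, 3], [1]), [1, 2, 3])

    def test_valid_direct_summation(self):
        assert np.allclose(conv1d_valid([1, 2, 3, 4], [1, 1]), [3, 5, 7])

    def test_valid_kernel_too_long(self):
        with pytest.raises(ValueError):
            conv1d_valid([1, 2], [1, 2, 3])

    @given(st.integers(2, 30), st.integers(1, 9))
    @settings(max_examples=30, deadline=None)
    def test_length_laws(self, n, k):
        if k > n:
            n, k = k, n
        rng = np.random.default_rng(n * 31 + k)
        s, w = rng.standard_normal(n), rng.standard_normal(k)
        assert len(conv1d_valid(s, w)) == n - k + 1
        assert len(conv1d_padded(s, w)) == n + k - 1

    def test_padded_direct_summation(self):
        assert np.allclose(conv1d_padded([1], [1, 1]), [1, 1])

    def test_padded_delta_kernel_shifts(self):
        s = np.array([1.0, 2.0, 3.0])
        out = conv1d_padded(s, np.array([1.0]))
        assert np.allclose(out, s)

    def test_padded_empty_rejected(self):
        with pytest.raises(ValueError):
            conv1d_padded([], [1])

    def test_valid_full_adjoint_pair(self):
        """⟨valid-corr(s, w), d⟩ = ⟨s, full-corr-adjoint⟩ via the padded op."""
        rng = np.random.default_rng(0)
        s, w = rng.standard_normal(11), rng.standard_normal(4)
        d = rng.standard_normal(11 - 4 + 1)
        lhs = conv1d_valid(s, w) @ d
        rhs = s @ conv1d_padded(d, w[::-1])
        assert lhs == pytest.approx(rhs)


class TestActivation:
    @pytest.mark.parametrize("x,fx,dfx", [
        (0.0, 0.0, 1.0),
        (2.0, 2.0, 1.0),
        (-1.0, np.expm1(-1.0), np.exp(-1.0)),
    ])
    def test_elu_closed_form(self, x, fx, dfx):
        assert elu(x) == pytest.approx(fx)
        assert elu_prime(x) == pytest.approx(dfx)

    def test_continuity_at_zero(self):
        eps = 1e-9
        assert abs(elu(eps) - elu(-eps)) < 1e-8
        assert abs(elu_prime(eps) - elu_prime(-eps)) < 1e-8


class TestPooling:
    def test_factor_one_identity(self):
        z = np.array([1.0, 2.0, 3.0])
        assert np.allclose(downsample(z, 1), z)
        assert np.allclose(upsample_zero_order(z, 1), z)

    def test_window_means(self):
        assert np.allclose(downsample([2, 4, 6, 8], 2), [3, 7])

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            downsample([1.0], 0)

    @given(st.integers(1, 5), st.integers(2, 40))
    @settings(max_examples=30, deadline=None)
    def test_adjointness(self, tt, n):
        """⟨downsample(z), d⟩ = ⟨z, upsample(d)⟩ (restricted to full windows)."""
        rng = np.random.default_rng(tt * 101 + n)
        z = rng.standard_normal(n)
        m = n // tt
        if m == 0:
            return
        d = rng.standard_normal(m)
        lhs = downsample(z, tt) @ d
        up = upsample_zero_order(d, tt)
        rhs = z[: m * tt] @ up
        assert lhs == pytest.approx(rhs)


class TestLoss:
    def test_zero_iff_equal(self):
        assert mse_loss([1, 0, 0, 0], [1, 0, 0, 0]) == 0.0

    def test_hand_value(self):
        assert mse_loss([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(2.0)

    def test_symmetry_and_mismatch(self):
        a, b = np.array([0.2, 0.5, 0.1, 0.9]), np.array([1.0, 0, 0, 0])
        assert mse_loss(a, b) == pytest.approx(mse_loss(b, a))
        with pytest.raises(ValueError):
            mse_loss([1, 2], [1, 2, 3])


def _total_loss(model, X, U):
    scores, _ = model.forward(X)
    return float(np.sum((scores - U) ** 2))


def _numeric_grad(model, X, U, param, idx, h=1e-5):
    old = param[idx]
    param[idx] = old + h
    up = _total_loss(model, X, U)
    param[idx] = old - h
    dn = _total_loss(model, X, U)
    param[idx] = old
    return (up - dn) / (2 * h)


class TestForward:
    def test_zero_weights_zero_scores(self):
        model = ODCNNModel(ODCNNConfig(depth=2, filters_per_layer=3, seed=0))
        for p in model.parameters():
            p[...] = 0.0
        scores, _ = model.forward(np.ones((5, 13)))
        assert np.allclose(scores, 0.0)

    def test_output_width_is_four(self):
        model = ODCNNModel(ODCNNConfig(seed=1))
        scores, _ = model.forward(np.zeros((3, 13)))
        assert scores.shape == (3, 4)

    def test_identity_conv_pooling_hand_case(self):
        """One 1-tap unit conv + mean pool + identity output = pooled input."""
        cfg = ODCNNConfig(depth=1, kernel_size=1, filters_per_layer=1,
                          pool_factor=2, mlp_hidden=(), padding_mode="valid",
                          input_len=8, seed=0)
        model = ODCNNModel(cfg)
        model.conv_groups[0].weights[...] = 1.0
        model.conv_groups[0].bias[...] = 0.0
        d = model.dense_layers[0]
        d.weights[...] = np.eye(4)
        d.bias[...] = 0.0
        x = np.array([[2.0, 4.0, 6.0, 8.0, 1.0, 3.0, 5.0, 7.0]])
        scores, _ = model.forward(x)
        assert np.allclose(scores, [[3.0, 7.0, 2.0, 6.0]])

    def test_shape_mismatch_rejected(self):
        model = ODCNNModel(ODCNNConfig(seed=0))
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 9)))

    def test_shrinking_network_guard(self):
        with pytest.raises(ValueError):
            ODCNNConfig(depth=5, kernel_size=7, padding_mode="valid").layer_lengths()


class TestBackward:
    @pytest.mark.parametrize("padding,tt", [("same", 1), ("same", 2),
                                            ("valid", 1), ("valid", 2)])
    def test_gradients_match_finite_differences(self, padding, tt):
        """Analytic backward equals central differences (rel err < 1e-4)."""
        cfg = ODCNNConfig(depth=2, kernel_size=3, filters_per_layer=3,
                          mlp_hidden=(5,), padding_mode=padding, pool_factor=tt,
                          input_len=13, seed=42)
        model = ODCNNModel(cfg)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((4, 13))
        U = np.eye(4)[rng.integers(0, 4, size=4)]
        scores, cache = model.forward(X)
        grads = model.backward(cache, scores, U)
        params = model.parameters()
        probe_rng = np.random.default_rng(9)
        checked = 0
        for p, g in zip(params, grads):
            for _ in range(5):
                idx = tuple(probe_rng.integers(0, s) for s in p.shape)
                num = _numeric_grad(model, X, U, p, idx)
                denom = max(abs(num), abs(g[idx]), 1e-8)
                assert abs(g[idx] - num) / denom < 1e-4
                checked += 1
        assert checked >= 20

    def test_zero_output_delta_gives_zero_grads(self):
        model = ODCNNModel(ODCNNConfig(depth=1, filters_per_layer=2,
                                       mlp_hidden=(4,), seed=0))
        X = np.random.default_rng(0).standard_normal((3, 13))
        scores, cache = model.forward(X)
        grads = model.backward(cache, scores, scores)  # target == output
        assert all(np.allclose(g, 0) for g in grads)

    def test_single_linear_neuron_closed_form(self):
        """For a linear map z = w·x, the gradient is 2(z−u)·x."""
        cfg = ODCNNConfig(depth=1, kernel_size=1, filters_per_layer=1,
                          pool_factor=1, mlp_hidden=(), padding_mode="valid",
                          input_len=4, seed=0)
        model = ODCNNModel(cfg)
        model.conv_groups[0].weights[...] = 1.0
        model.conv_groups[0].bias[...] = 0.0
        x = np.array([[0.5, 1.5, 2.5, 3.5]])
        u = np.array([[0.0, 1.0, 0.0, 0.0]])
        scores, cache = model.forward(x)
        grads = model.backward(cache, scores, u)
        gW_dense = grads[2]
        expected = 2 * (scores - u).T @ x
        assert np.allclose(gW_dense, expected)

    def test_missing_cache_rejected(self):
        model = ODCNNModel(ODCNNConfig(seed=0))
        with pytest.raises(RuntimeError):
            model.backward({}, np.zeros((1, 4)), np.zeros((1, 4)))


class TestSgdUpdate:
    def test_zero_lr_no_change(self):
        model = ODCNNModel(ODCNNConfig(depth=1, seed=0))
        before = [p.copy() for p in model.parameters()]
        X = np.random.default_rng(1).standard_normal((2, 13))
        scores, cache = model.forward(X)
        grads = model.backward(cache, scores, np.eye(4)[[0, 1]])
        model.sgd_update(grads, 0.0)
        assert all(np.array_equal(a, b) for a, b in zip(before, model.parameters()))

    def test_two_steps_equal_summed_gradients_for_fixed_grads(self):
        model = ODCNNModel(ODCNNConfig(depth=1, seed=0))
        g1 = [np.ones_like(p) for p in model.parameters()]
        ref = ODCNNModel(ODCNNConfig(depth=1, seed=0))
        model.sgd_update(g1, 0.1)
        model.sgd_update(g1, 0.1)
        ref.sgd_update([2 * g for g in g1], 0.1)
        assert all(np.allclose(a, b) for a, b in
                   zip(model.parameters(), ref.parameters()))

    def test_non_finite_gradients_abort(self):
        model = ODCNNModel(ODCNNConfig(depth=1, seed=0))
        bad = [np.full_like(p, np.nan) for p in model.parameters()]
        with pytest.raises(TrainingDivergedError):
            model.sgd_update(bad, 0.1)


class TestTraining:
    def test_separable_toy_reaches_full_accuracy(self, separable_toy):
        X, y = separable_toy
        cfg = ODCNNConfig(depth=1, kernel_size=3, filters_per_layer=4,
                          mlp_hidden=(8,), epochs=200, batch_size=16,
                          learning_rate=0.01, seed=0)
        _, report = odcnn.train(X, y, cfg)
        assert report.accuracy == 1.0

    def test_determinism(self, separable_toy, tiny_cnn_config):
        X, y = separable_toy
        m1, _ = odcnn.train(X, y, tiny_cnn_config)
        m2, _ = odcnn.train(X, y, tiny_cnn_config)
        assert all(np.array_equal(a, b)
                   for a, b in zip(m1.parameters(), m2.parameters()))

    def test_loss_decreases(self, separable_toy, tiny_cnn_config):
        X, y = separable_toy
        _, report = odcnn.train(X, y, tiny_cnn_config)
        curve = report.loss_curve
        head = np.mean(curve[: max(1, len(curve) // 10)])
        tail = np.mean(curve[-max(1, len(curve) // 10):])
        assert tail < head

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            odcnn.train(np.zeros((10, 13)), np.zeros(10, dtype=int), ODCNNConfig())


class TestPredictAndSerialization:
    def test_argmax_consistency_and_score_width(self, separable_toy, tiny_cnn_config):
        X, y = separable_toy
        model, _ = odcnn.train(X, y, tiny_cnn_config)
        labels, scores = model.predict(X)
        assert scores.shape[1] == 4
        assert np.array_equal(labels, scores.argmax(axis=1))

    def test_json_round_trip_exact(self, tiny_cnn_config):
        model = ODCNNModel(tiny_cnn_config)
        back = ODCNNModel.from_json(model.to_json())
        assert all(np.array_equal(a, b)
                   for a, b in zip(model.parameters(), back.parameters()))
        X = np.random.default_rng(0).standard_normal((3, 13))
        assert np.array_equal(model.predict(X)[1], back.predict(X)[1])


class TestCrossValidationAndGrid:
    def test_confusion_rows_partition_class_counts(self, separable_toy, tiny_cnn_config):
        X, y = separable_toy
        report = odcnn.cross_validate(X, y, tiny_cnn_config, k=4)
        assert np.array_equal(report.confusion.sum(axis=1), np.bincount(y))
        assert report.n == len(y)

    def test_too_few_members_rejected(self, tiny_cnn_config):
        X = np.zeros((6, 13))
        y = np.array([0, 0, 0, 1, 2, 3])
        with pytest.raises(ValueError):
            odcnn.cross_validate(X, y, tiny_cnn_config, k=3)

    def test_grid_of_one(self, separable_toy, tiny_cnn_config):
        X, y = separable_toy
        best, table = odcnn.grid_search(X, y, [tiny_cnn_config], k=3)
        assert best is tiny_cnn_config
        assert len(table) == 1

    def test_crippled_config_loses(self, separable_toy, tiny_cnn_config):
        X, y = separable_toy
        import dataclasses
        crippled = dataclasses.replace(tiny_cnn_config, learning_rate=10.0, epochs=5)
        sane = dataclasses.replace(tiny_cnn_config, epochs=40)
        best, _ = odcnn.grid_search(X, y, [crippled, sane], k=3)
        assert best is sane

    def test_standard_grid_shape(self):
        grid = odcnn.standard_grid()
        assert len(grid) == 16
        assert {c.depth for c in grid} == {3, 4, 5, 6}
        assert grid[10].depth == 5 and grid[10].kernel_size == 7
        assert grid[10].learning_rate == pytest.approx(0.0005)
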