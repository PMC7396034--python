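"""Network algebra: layer oracles, gradient checks, training behaviour."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from convbag.convnet import (Network, TrainConfig, conv_backward, conv_forward,
                             cross_entropy, default_network_spec,
                             dense_backward, dense_forward, extract_features,
                             gradient_check, max_pool_forward,
                             mini_network_spec, pool_backward, predict_softmax,
                             softmax, train_network, update_params)
from convbag.errors import ArchitectureError, ConfigurationError


# ---------------------------------------------------------------------------
# forward-pass oracles
# ---------------------------------------------------------------------------

class TestConvForward:
    def test_same_padding_preserves_spatial_dims(self, rng):
        x = rng.normal(size=(2, 6, 6, 1))
        W = rng.normal(size=(3, 3, 1, 32))
        a, z, _ = conv_forward(x, W, np.zeros(32))
        assert a.shape == (2, 6, 6, 32)

    def test_zero_kernels_output_relu_of_bias(self, rng):
        x = rng.normal(size=(1, 6, 6, 1))
        W = np.zeros((3, 3, 1, 4))
        b = np.array([1.5, -2.0, 0.0, 3.0])
        a, _, _ = conv_forward(x, W, b)
        for c, beta in enumerate(b):
            np.testing.assert_allclose(a[..., c], max(beta, 0.0))

    def test_valid_ones_kernel_computes_window_sums(self):
        x = np.arange(9, dtype=float).reshape(1, 3, 3, 1)
        W = np.ones((2, 2, 1, 1))
        _, z, _ = conv_forward(x, W, np.zeros(1), padding="valid")
        expected = np.array([[0 + 1 + 3 + 4, 1 + 2 + 4 + 5],
                             [3 + 4 + 6 + 7, 4 + 5 + 7 + 8]], dtype=float)
        np.testing.assert_array_equal(z[0, :, :, 0], expected)

    def test_matches_scipy_correlate_oracle(self, rng):
        """Cross-correlation convention verified against scipy."""
        x = rng.normal(size=(1, 5, 5, 1))
        W = rng.normal(size=(3, 3, 1, 1))
        _, z, _ = conv_forward(x, W, np.zeros(1), padding="valid")
        ref = correlate2d(x[0, :, :, 0], W[:, :, 0, 0], mode="valid")
        np.testing.assert_allclose(z[0, :, :, 0], ref, rtol=1e-12)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ArchitectureError):
            conv_forward(rng.normal(size=(1, 6, 6, 2)),
                         rng.normal(size=(3, 3, 1, 8)), np.zeros(8))


class TestMaxPool:
    def test_stride_one_shrinks_by_one(self, rng):
        x = rng.normal(size=(3, 6, 6, 32))
        out, _ = max_pool_forward(x, window=2, stride=1)
        assert out.shape == (3, 5, 5, 32)

    def test_constant_input_stays_constant(self):
        x = np.full((1, 4, 4, 1), 2.5)
        out, cache = max_pool_forward(x)
        np.testing.assert_array_equal(out, np.full((1, 3, 3, 1), 2.5))
        # ties resolve to the first window position in row-major order
        assert (cache["amax"] == 0).all()

    def test_two_by_two_window_takes_the_max(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
        out, _ = max_pool_forward(x)
        assert out.item() == 4.0

    def test_window_larger_than_input_raises(self):
        with pytest.raises(ArchitectureError):
            max_pool_forward(np.zeros((1, 1, 1, 1)), window=2)


class TestDense:
    def test_identity_map(self):
        a = np.array([[1.0, -2.0, 3.0]])
        out, z = dense_forward(a, np.eye(3), np.zeros(3), activation="linear")
        np.testing.assert_array_equal(z, a)

    def test_softmax_symmetry_and_closed_form(self):
        np.testing.assert_allclose(softmax(np.array([[0.0, 0.0]])), [[0.5, 0.5]])
        np.testing.assert_allclose(
            softmax(np.array([[np.log(1.0), np.log(3.0)]])), [[0.25, 0.75]])

    def test_softmax_is_stable_for_huge_logits(self):
        probs = softmax(np.array([[1000.0, 999.0]]))
        assert np.isfinite(probs).all()
        np.testing.assert_allclose(probs.sum(), 1.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ArchitectureError):
            dense_forward(np.ones((1, 4)), np.ones((2, 3)), np.zeros(2))


# ---------------------------------------------------------------------------
# backward-pass behaviour
# ---------------------------------------------------------------------------

class TestBackward:
    def test_zero_incoming_error_propagates_zero(self, rng):
        z = rng.normal(size=(4, 7))
        delta = dense_backward(np.zeros((4, 5)), rng.normal(size=(5, 7)), z)
        np.testing.assert_array_equal(delta, 0.0)

    def test_dead_relu_units_block_the_error(self, rng):
        z = -np.abs(rng.normal(size=(4, 7)))      # all negative
        delta = dense_backward(rng.normal(size=(4, 5)),
                               rng.normal(size=(5, 7)), z)
        np.testing.assert_array_equal(delta, 0.0)

    def test_conv_zero_delta_gives_zero_gradients(self, rng):
        x = rng.normal(size=(2, 4, 4, 1))
        W = rng.normal(size=(2, 2, 1, 3))
        _, _, cache = conv_forward(x, W, np.zeros(3), padding="valid")
        dx, dW, db = conv_backward(np.zeros((2, 3, 3, 3)), W, cache)
        assert not dx.any() and not dW.any() and not db.any()

    def test_conv_bias_gradient_is_spatial_sum_of_delta(self, rng):
        x = rng.normal(size=(2, 4, 4, 1)) + 5.0    # keep ReLU active
        W = np.abs(rng.normal(size=(2, 2, 1, 3)))
        _, _, cache = conv_forward(x, W, np.zeros(3), padding="valid")
        d_a = rng.normal(size=(2, 3, 3, 3))
        _, _, db = conv_backward(d_a, W, cache)
        np.testing.assert_allclose(db, d_a.sum(axis=(0, 1, 2)), rtol=1e-12)

    def test_pool_backward_conserves_error_mass(self, rng):
        x = rng.normal(size=(2, 5, 5, 3))
        _, cache = max_pool_forward(x, window=2, stride=1)
        d_out = rng.normal(size=(2, 4, 4, 3))
        d_in = pool_backward(d_out, cache)
        np.testing.assert_allclose(d_in.sum(), d_out.sum(), rtol=1e-12)

    def test_single_global_max_collects_all_window_errors(self):
        x = np.zeros((1, 3, 3, 1))
        x[0, 1, 1, 0] = 10.0                       # inside all four 2x2 windows
        _, cache = max_pool_forward(x, window=2, stride=1)
        d_out = np.arange(1.0, 5.0).reshape(1, 2, 2, 1)
        d_in = pool_backward(d_out, cache)
        assert d_in[0, 1, 1, 0] == pytest.approx(10.0)    # 1+2+3+4
        assert d_in.sum() == pytest.approx(10.0)

    def test_non_overlapping_windows_route_to_argmax_only(self, rng):
        x = rng.normal(size=(1, 4, 4, 1))
        out, cache = max_pool_forward(x, window=2, stride=2)
        d_out = np.ones((1, 2, 2, 1))
        d_in = pool_backward(d_out, cache)
        assert (d_in != 0).sum() == 4
        np.testing.assert_array_equal(np.sort(d_in[d_in != 0]), np.ones(4))


class TestUpdates:
    def test_zero_learning_rate_is_identity(self, rng):
        params = {"W": rng.normal(size=(3, 3)), "b": rng.normal(size=3)}
        grads = {"W": rng.normal(size=(3, 3)), "b": rng.normal(size=3)}
        out = update_params(params, grads, 0.0)
        for k in params:
            np.testing.assert_array_equal(out[k], params[k])

    def test_scalar_step_matches_definition(self):
        out = update_params({"w": np.array([2.0])}, {"w": np.array([0.5])}, 0.1)
        assert out["w"].item() == pytest.approx(2.0 - 0.1 * 0.5)

    def test_batch_gradient_is_the_sum_of_per_sample_gradients(self, rng):
        """Updates use the summed (not averaged) per-sample gradients."""
        spec = mini_network_spec()
        net = Network(spec).init_params(seed=0)
        x = rng.normal(size=(2, 4, 4, 1))
        y = np.eye(2)[[0, 1]]
        net.forward(x, keep_cache=True)
        batch_grads = net.backward(y)
        singles = []
        for i in range(2):
            net.forward(x[i:i + 1], keep_cache=True)
            singles.append(net.backward(y[i:i + 1]))
        for k in batch_grads:
            np.testing.assert_allclose(
                batch_grads[k], singles[0][k] + singles[1][k], rtol=1e-9, atol=1e-12)

    def test_non_finite_gradient_raises(self):
        from convbag.errors import DivergenceError
        with pytest.raises(DivergenceError):
            update_params({"w": np.ones(1)}, {"w": np.array([np.nan])}, 0.1)


# ---------------------------------------------------------------------------
# whole-network properties
# ---------------------------------------------------------------------------

def test_full_gradient_check_on_miniature_network():
    """Analytic gradients match central finite differences on every parameter."""
    for seed in range(5):
        assert gradient_check(seed=seed, step=1e-5) < 1e-5


def test_shape_trace_matches_the_published_layout():
    trace = default_network_spec().shape_trace()
    assert trace == [(6, 6, 1), (6, 6, 32), (5, 5, 32), (5, 5, 64),
                     (4, 4, 64), (1024,), (128,), (128,), (2,)]


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_data(self):
        gen = np.random.default_rng(7)
        x = gen.normal(size=(64, 4, 4, 1))
        y_idx = (x.sum(axis=(1, 2, 3)) > 0).astype(int)
        return x, np.eye(2)[y_idx], y_idx

    def test_infinite_tolerance_stops_after_one_iteration(self, toy_data):
        x, y, _ = toy_data
        cfg = TrainConfig(max_iterations=50, tolerance=np.inf, seed=0)
        _, history = train_network(mini_network_spec(), x, y, cfg)
        assert history.iteration == [1]

    def test_zero_learning_rate_leaves_params_bit_identical(self, toy_data):
        x, y, _ = toy_data
        cfg = TrainConfig(learning_rate=0.0, max_iterations=5, seed=3)
        net, _ = train_network(mini_network_spec(), x, y, cfg)
        fresh = Network(mini_network_spec()).init_params(seed=3)
        np.testing.assert_array_equal(net.param_vector(), fresh.param_vector())

    def test_same_seed_trains_identically(self, toy_data):
        x, y, _ = toy_data
        cfg = TrainConfig(max_iterations=20, seed=11)
        a, _ = train_network(mini_network_spec(), x, y, cfg)
        b, _ = train_network(mini_network_spec(), x, y, cfg)
        np.testing.assert_array_equal(a.param_vector(), b.param_vector())

    def test_bad_label_shape_raises(self, toy_data):
        x, _, y_idx = toy_data
        with pytest.raises(ConfigurationError):
            train_network(mini_network_spec(), x,
                          y_idx.astype(float).reshape(-1, 1), TrainConfig())

    def test_loss_decreases_with_small_full_batch_steps(self, separable_small):
        """Full-batch descent at a small step is monotone early in training."""
        from convbag.preprocess import (encode_grid, rank_feature_importance,
                                        select_features)
        ds = separable_small
        ranking = rank_feature_importance(ds.table, seed=5, n_trees=20,
                                          n_repeats=1)
        grids = encode_grid(select_features(ds.table, ranking, 36))
        y = np.eye(2)[ds.table.binary_label()]
        cfg = TrainConfig(learning_rate=1e-6, max_iterations=10,
                          batch_size=ds.table.n_rows, seed=0)
        _, history = train_network(default_network_spec(), grids.data, y, cfg)
        assert all(b <= a + 1e-12 for a, b in zip(history.loss, history.loss[1:]))


class TestInference:
    @pytest.fixture(scope="class")
    def trained_mini(self):
        gen = np.random.default_rng(5)
        x = gen.normal(size=(40, 4, 4, 1))
        y = np.eye(2)[gen.integers(0, 2, 40)]
        net, _ = train_network(mini_network_spec(), x, y,
                               TrainConfig(max_iterations=30, seed=1))
        return net, x

    def test_feature_matrix_shape_and_range(self, trained_mini):
        net, x = trained_mini
        feats = extract_features(net, x)
        assert feats.shape == (40, 8)             # mini spec's dense width
        assert (feats >= 0).all()                  # ReLU activations

    def test_identical_rows_give_identical_features(self, trained_mini):
        net, x = trained_mini
        pair = np.repeat(x[:1], 2, axis=0)
        feats = extract_features(net, pair)
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_probabilities_sum_to_one(self, trained_mini):
        net, x = trained_mini
        _, probs = predict_softmax(net, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_logits_break_to_class_zero(self):
        net = Network(mini_network_spec()).init_params(seed=0)
        for k in list(net.params):
            net.params[k] = np.zeros_like(net.params[k])   # all logits equal
        labels, probs = predict_softmax(net, np.ones((3, 4, 4, 1)))
        np.testing.assert_allclose(probs, 0.5)
        assert (labels == 0).all()

    def test_default_extractor_width_is_128(self, separable_small):
        from convbag.preprocess import (encode_grid, rank_feature_importance,
                                        select_features)
        ds = separable_small
        ranking = rank_feature_importance(ds.table, seed=5, n_trees=10,
                                          n_repeats=1)
        grids = encode_grid(select_features(ds.table, ranking, 36))
        y = np.eye(2)[ds.table.binary_label()]
        net, _ = train_network(default_network_spec(), grids.data, y,
                               TrainConfig(max_iterations=2, seed=0))
        assert extract_features(net, grids.data[:7]).shape == (7, 128)

    def test_cross_entropy_of_perfect_prediction_is_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.eye(2)
        assert cross_entropy(probs, y) == pytest.approx(0.0, abs=1e-10)
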