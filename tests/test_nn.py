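"""Dense P3D classifier: blocks, shape algebra, training, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holocyte.nn import (
    DecisionThreshold,
    DenseP3DBlock,
    NetworkConfig,
    TrainConfig,
    build_network,
    classify,
    threshold_grid,
    train,
    tune_decision_threshold,
)
from holocyte.nn.layers import BatchNorm3d, Conv3d, MaxPool3d


class TestLayers:
    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        conv = Conv3d(3, 4, (3, 1, 1), stride=1, padding=(1, 0, 0))
        conv.weight.value = rng.normal(0, 0.3, conv.weight.value.shape).astype(np.float32)
        x = rng.normal(size=(2, 3, 5, 5, 5)).astype(np.float32)
        R = rng.normal(size=conv.forward(x).shape)

        def loss():
            return float((conv.forward(x).astype(np.float64) * R).sum())

        conv.forward(x)
        conv.weight.grad[:] = 0
        conv.backward(R.astype(np.float32))
        flat, g = conv.weight.value.reshape(-1), conv.weight.grad.reshape(-1)
        for j in rng.integers(0, flat.size, 6):
            eps, old = 1e-2, flat[j]
            flat[j] = old + eps
            lp = loss()
            flat[j] = old - eps
            lm = loss()
            flat[j] = old
            assert abs((lp - lm) / (2 * eps) - g[j]) < 1e-3 * max(1, abs(g[j]))

    def test_batchnorm_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        bn = BatchNorm3d(3)
        bn.train_mode = True
        x = rng.normal(size=(2, 3, 4, 4, 4)).astype(np.float32)
        R = rng.normal(size=x.shape)

        def loss():
            return float((bn.forward(x).astype(np.float64) * R).sum())

        bn.forward(x)
        bn.gamma.grad[:] = 0
        bn.backward(R.astype(np.float32))
        for j in range(3):
            eps, old = 1e-2, bn.gamma.value[j]
            bn.gamma.value[j] = old + eps
            lp = loss()
            bn.gamma.value[j] = old - eps
            lm = loss()
            bn.gamma.value[j] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - bn.gamma.grad[j]) < 1e-3 * max(1, abs(num))

    def test_maxpool_halves_and_routes_gradient(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
        pool = MaxPool3d()
        y = pool.forward(x)
        assert y.shape == (1, 2, 2, 2, 2)
        # brute-force window maxima
        for c in range(2):
            for i, j, k in np.ndindex(2, 2, 2):
                win = x[0, c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2]
                assert y[0, c, i, j, k] == win.max()
        dy = np.ones_like(y)
        dx = pool.backward(dy)
        assert dx.sum() == y.size  # exactly one unit routed per window


class TestDenseBlock:
    @given(c=st.integers(1, 12), k=st.integers(1, 8))
    @settings(max_examples=15, deadline=None)
    def test_channel_bookkeeping(self, c, k):
        block = DenseP3DBlock(c, k)
        x = np.random.default_rng(0).normal(size=(1, c, 4, 4, 4)).astype(np.float32)
        assert block.forward(x).shape[1] == c + 2 * k == block.out_channels

    def test_extent_halving(self):
        block = DenseP3DBlock(16, 8)
        x = np.zeros((1, 16, 40, 32, 32), np.float32)
        assert block.forward(x).shape == (1, 32, 20, 16, 16)

    def test_zero_weight_block_is_pooled_concat(self):
        # with zero convolution weights and the rectifier forced open, the
        # block reduces to max pooling of [0-channels, input]; checked on a
        # 1 x 4 x 4 x 4 example against a hand-computed pooled concat
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32)
        block = DenseP3DBlock(1, 2)
        for stage in (block.conv_s, block.conv_t):
            stage.conv.weight.value[:] = 0.0
            stage.conv.bias.value[:] = 0.0
        y = block.forward(x)
        assert y.shape == (1, 5, 2, 2, 2)
        # channels 0..3 come from zeroed convolutions -> pooled zeros
        assert np.all(y[0, :2] == 0.0) and np.all(y[0, 2:3] == 0.0)
        # last channel: hand-computed 2x2x2 max pool of the input
        expected = np.empty((2, 2, 2), np.float32)
        for i, j, k in np.ndindex(2, 2, 2):
            expected[i, j, k] = x[0, 0, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2,
                                  2 * k : 2 * k + 2].max()
        assert np.allclose(y[0, -1], expected)

    def test_non_poolable_extent_rejected(self):
        block = DenseP3DBlock(2, 2)
        with pytest.raises(ValueError):
            block.forward(np.zeros((1, 2, 1, 4, 4), np.float32))


class TestBuildNetwork:
    def test_default_shape_trace(self):
        net = build_network(NetworkConfig())
        trace = dict(net.shape_trace)
        assert trace["stem_spatial"] == (16, 120, 32, 32)
        assert trace["stem_temporal"] == (16, 40, 32, 32)
        assert trace["dense_block_2"] == (48, 10, 8, 8)
        assert trace["mid_conv"] == (48, 8, 8, 8)
        assert trace["dense_block_5"] == (96, 1, 1, 1)

    def test_forward_probabilities_sum_to_one(self):
        net = build_network(NetworkConfig.desk_scale())
        net.initialize(np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(3, 2, 24, 16, 16))
        p = net.predict_proba(x)
        assert p.shape == (3, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_batching(self):
        net = build_network(NetworkConfig.desk_scale())
        x = np.zeros((3, 2, 24, 16, 16))
        assert net.forward(x).shape == (3, 2)

    def test_invalid_architecture_names_stage(self):
        cfg = NetworkConfig(n_frames=8, height=8, width=8)  # cannot reach 1x1x1
        with pytest.raises(ValueError, match="stage"):
            build_network(cfg)

    def test_truncated_normal_init(self):
        net = build_network(NetworkConfig.desk_scale())
        net.initialize(np.random.default_rng(0), std=0.05)
        conv = next(l for l in net.layers if isinstance(l, Conv3d))
        w = conv.weight.value
        assert np.abs(w).max() <= 2 * 0.05 + 1e-9
        assert w.std() > 0.02
        fc = net.layers[-1]
        assert np.all(fc.weight.value == 0.0)


class TestTraining:
    def _toy_data(self, n_per_class=5, seed=0):
        rng = np.random.default_rng(seed)
        x0 = rng.normal(0, 0.3, (n_per_class, 2, 24, 16, 16))
        x0[:, 0, :, 4:8, 4:8] += 1.0
        x1 = rng.normal(0, 0.3, (n_per_class, 2, 24, 16, 16))
        x1[:, 0, :, 8:12, 8:12] += 1.0
        X = np.concatenate([x0, x1]).astype(np.float32)
        y = np.array([0] * n_per_class + [1] * n_per_class)
        return X, y

    def test_overfits_toy_set(self):
        X, y = self._toy_data()
        net = build_network(NetworkConfig.desk_scale())
        train(net, X, y, TrainConfig(learning_rate=1e-3, batch_size=10,
                                     epochs=60, augment=False, seed=0))
        labels, _ = classify(net, X, 0.5)
        assert (labels == (y == 1)).mean() == 1.0

    def test_deterministic_given_seed(self):
        X, y = self._toy_data()
        cfg = TrainConfig(learning_rate=1e-3, batch_size=10, epochs=1, seed=7)
        h1 = train(build_network(NetworkConfig.desk_scale()), X, y, cfg)
        h2 = train(build_network(NetworkConfig.desk_scale()), X, y, cfg)
        assert h1.loss.iloc[0] == h2.loss.iloc[0]

    def test_single_class_rejected(self):
        X, _ = self._toy_data()
        net = build_network(NetworkConfig.desk_scale())
        with pytest.raises(ValueError):
            train(net, X, np.zeros(len(X), dtype=int))


class TestDecisionThreshold:
    def test_separated_scores_give_half_then_safety(self):
        scores = np.array([0.1, 0.2, 0.4, 0.6, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        thr = tune_decision_threshold(scores, labels)
        assert thr.value == 0.9  # 0.5 admits zero FP; safety moves one decade
        assert thr.safety_applied

    def test_grid_scan_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.uniform(0, 0.995, 50), rng.uniform(0.9, 1.0, 20)])
        scores[17] = 0.995  # controlled negative maximum
        labels = np.array([0] * 50 + [1] * 20)
        thr = tune_decision_threshold(scores, labels, safety_steps=0)
        grid = threshold_grid()
        oracle = next(t for t in grid
                      if ((scores[labels == 0] >= t).sum() == 0))
        assert thr.value == oracle == 0.999
        assert tune_decision_threshold(scores, labels).value == 0.9999

    def test_negative_scoring_one_rejected(self):
        with pytest.raises(ValueError):
            tune_decision_threshold(np.array([1.0, 0.9]), np.array([0, 1]))

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError):
            tune_decision_threshold(np.array([0.9, 0.8]), np.array([1, 1]))

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            DecisionThreshold(0.4)
        with pytest.raises(ValueError):
            DecisionThreshold(1.0)

    @given(thr_idx=st.integers(0, 8))
    @settings(max_examples=9, deadline=None)
    def test_positives_called_nonincreasing_in_threshold(self, thr_idx):
        rng = np.random.default_rng(13)
        scores = rng.uniform(0, 1, 200)
        grid = threshold_grid()
        n_now = (scores >= grid[thr_idx]).sum()
        n_next = (scores >= grid[thr_idx + 1]).sum()
        assert n_next <= n_now


@pytest.fixture(scope="module")
def model():
    net = build_network(NetworkConfig.desk_scale())
    net.initialize(np.random.default_rng(0))
    return net


class TestClassify:

    def test_boundary_convention(self, model):
        # probability exactly at the threshold is called positive
        labels, probs = classify(model, np.zeros((2, 2, 24, 16, 16)), 0.5)
        assert np.all(labels == (probs >= 0.5))

    def test_high_threshold_rejects_sub_threshold_probability(self):
        thr = DecisionThreshold(0.999999)
        assert not (0.9999 >= thr.value)  # the operating-point contract

    def test_empty_input(self, model):
        labels, probs = classify(model, np.zeros((0, 2, 24, 16, 16)))
        assert labels.size == 0 and probs.size == 0

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            classify(model, np.zeros((1, 2, 10, 16, 16)))
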