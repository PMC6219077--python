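"""Classifier architecture, loss, optimizer and training contracts."""

import numpy as np
import pytest

from fundusdr import (
    InvalidInputError,
    NetworkConfig,
    TrainingConfig,
    build_network,
    cross_entropy_loss,
    predict_patch,
    sgd_update,
)
from fundusdr.errors import InvalidConfigError
from fundusdr.nn.layers import softmax
from fundusdr.nn.loss import softmax_cross_entropy_grad


class TestArchitecture:
    def test_forward_pass_is_probability_vector(self, default_model):
        rng = np.random.default_rng(0)
        patch = rng.uniform(0, 255, (50, 50, 3))
        probs = predict_patch(default_model, patch)
        assert probs.shape == (4,)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert abs(probs.sum() - 1.0) < 1e-6

    def test_feature_map_chain_for_50px_input(self):
        # repeated floor(n/2): 50 -> 25 -> 12 -> 6 -> 3
        cfg = NetworkConfig()
        assert cfg.flat_features == 3 * 3 * cfg.feature_maps
        model = build_network(cfg, seed=0)
        x = np.zeros((1, 50, 50, 3), dtype=np.float32)
        sides = []
        for layer in model.layers:
            x = layer.forward(x)
            if type(layer).__name__ == "MaxPool2D":
                sides.append(x.shape[1])
        assert sides == [25, 12, 6, 3]

    def test_each_conv_block_has_16_feature_maps(self, default_model):
        convs = [l for l in default_model.layers if type(l).__name__ == "Conv2D"]
        assert len(convs) == 4
        assert all(c.out_ch == 16 for c in convs)

    def test_dropout_rate_is_half(self, default_model):
        (drop,) = [l for l in default_model.layers if type(l).__name__ == "Dropout"]
        assert drop.rate == 0.5

    def test_inference_is_deterministic_despite_dropout(self, default_model):
        rng = np.random.default_rng(1)
        patch = rng.uniform(0, 255, (50, 50, 3))
        a = predict_patch(default_model, patch)
        b = predict_patch(default_model, patch)
        assert np.array_equal(a, b)

    def test_too_small_input_side_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_network(NetworkConfig(input_side=15))

    def test_wrong_patch_size_rejected(self, default_model):
        with pytest.raises(InvalidInputError):
            predict_patch(default_model, np.zeros((30, 30, 3)))

    def test_equal_logits_give_uniform_probabilities(self):
        assert np.allclose(softmax(np.zeros((1, 4))), 0.25)

    def test_checkpoint_round_trip(self, tmp_path, small_model):
        rng = np.random.default_rng(2)
        patch = rng.uniform(0, 255, (24, 24, 3))
        before = predict_patch(small_model, patch)
        path = tmp_path / "model.npz"
        small_model.save(path)
        from fundusdr import Network

        reloaded = Network.load(path)
        assert np.allclose(predict_patch(reloaded, patch), before)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[0.0, 1.0, 0.0, 0.0]])
        assert cross_entropy_loss(probs, [1]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_ln4(self):
        probs = np.full((5, 4), 0.25)
        assert cross_entropy_loss(probs, [0, 1, 2, 3, 0]) == pytest.approx(np.log(4))

    def test_mean_of_log_probs(self):
        # true-class probabilities e^-1 and e^-3 -> mean loss (1+3)/2 = 2
        p1, p3 = np.exp(-1), np.exp(-3)
        probs = np.array([
            [p1, *( [(1 - p1) / 3] * 3 )],
            [p3, *( [(1 - p3) / 3] * 3 )],
        ])
        assert cross_entropy_loss(probs, [0, 0]) == pytest.approx(2.0)

    def test_invariant_to_sample_order(self, rng):
        probs = rng.dirichlet(np.ones(4), size=20)
        labels = rng.integers(0, 4, 20)
        perm = rng.permutation(20)
        assert cross_entropy_loss(probs, labels) == pytest.approx(
            cross_entropy_loss(probs[perm], labels[perm])
        )

    def test_label_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            cross_entropy_loss(np.full((1, 4), 0.25), [4])

    def test_non_normalized_rows_rejected(self):
        with pytest.raises(InvalidInputError):
            cross_entropy_loss(np.array([[0.5, 0.1, 0.1, 0.1]]), [0])


class TestSgdUpdate:
    def test_plain_gradient_step(self):
        theta, vel = sgd_update(2.0, 0.5, lr=0.1)
        assert theta == pytest.approx(2.0 - 0.05)

    def test_zero_gradient_fixed_point(self):
        theta, vel = sgd_update(1.5, 0.0, lr=0.1)
        assert theta == 1.5 and vel == 0.0

    def test_hand_computed_scalar_step(self):
        # theta' = 1 - 0.1*0.5 + 0.9*(-0.02) - 0.1*0.1*1 = 0.922
        theta, vel = sgd_update(
            1.0, 0.5, lr=0.1, momentum=0.9, weight_decay=0.1, velocity=-0.02
        )
        assert theta == pytest.approx(0.922, abs=1e-12)
        assert vel == pytest.approx(-0.078, abs=1e-12)

    def test_velocity_is_applied_step(self, rng):
        theta0 = rng.normal(size=(3, 2))
        grad = rng.normal(size=(3, 2))
        theta1, vel = sgd_update(theta0, grad, lr=0.05, momentum=0.9,
                                 weight_decay=1e-3, velocity=np.zeros((3, 2)))
        assert np.allclose(vel, theta1 - theta0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            sgd_update(np.zeros(3), np.zeros(4), lr=0.1)

    def test_descent_on_quadratic(self):
        # one step with small lr reduces f(theta) = 0.5 theta^2
        theta = 3.0
        for _ in range(5):
            new, _ = sgd_update(theta, theta, lr=0.1)
            assert 0.5 * new**2 < 0.5 * theta**2
            theta = new


class TestGradients:
    """Numerical gradient checks pin every layer's backward pass."""

    @staticmethod
    def tiny_model(norm):
        cfg = NetworkConfig(input_side=16, feature_maps=4, fc_units=8,
                            dropout_rate=0.0, norm=norm)
        return build_network(cfg, init_std=0.1, seed=1, dtype=np.float64)

    @pytest.mark.parametrize("norm", ["lrn", "batch", "none"])
    def test_parameter_gradients(self, norm):
        model = self.tiny_model(norm)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 16, 16, 3))
        y = np.array([0, 2, 3])

        def loss_of():
            probs = softmax(model.forward(x, train=True))
            return cross_entropy_loss(probs, y), probs

        _, probs = loss_of()
        model.backward(softmax_cross_entropy_grad(probs, y))
        for name, layer, key in model.parameters():
            w, g = layer.params[key], layer.grads[key]
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in w.shape)
                eps, old = 1e-6, w[idx]
                w[idx] = old + eps
                lp, _ = loss_of()
                w[idx] = old - eps
                lm, _ = loss_of()
                w[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 1e-5 * max(1.0, abs(num)), name

    def test_input_gradient_through_lrn(self):
        model = self.tiny_model("lrn")
        model.layers[0].needs_input_grad = True  # propagate down to the input
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 16, 16, 3))
        y = np.array([1, 2])

        def loss_of():
            return cross_entropy_loss(softmax(model.forward(x, train=True)), y)

        probs = softmax(model.forward(x, train=True))
        dx = model.backward(softmax_cross_entropy_grad(probs, y))
        for _ in range(4):
            idx = tuple(int(rng.integers(s)) for s in x.shape)
            eps, old = 1e-6, x[idx]
            x[idx] = old + eps
            lp = loss_of()
            x[idx] = old - eps
            lm = loss_of()
            x[idx] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - dx[idx]) < 1e-5 * max(1.0, abs(num))


class TestTrainingLoop:
    @staticmethod
    def separable_patches(n_per_class, side=24, seed=0):
        from fundusdr.synthetic import FixtureConfig, generate_separable_patches

        cfg = FixtureConfig(microaneurysm_radius=(2.0, 3.0))
        return generate_separable_patches(n_per_class, patch_size=side, seed=seed,
                                          config=cfg)

    @staticmethod
    def nearest_mean_oracle(train, test):
        """Nearest class-centroid classifier in mean-RGB space."""
        import collections

        sums = collections.defaultdict(list)
        for p in train:
            sums[p.label].append(p.window.mean(axis=(0, 1)))
        centroids = {k: np.mean(v, axis=0) for k, v in sums.items()}
        correct = 0
        for p in test:
            feats = p.window.mean(axis=(0, 1))
            pred = min(centroids, key=lambda k: np.linalg.norm(centroids[k] - feats))
            correct += pred == p.label
        return correct / len(test)

    def test_training_reaches_090_on_separable_fixture(self):
        from fundusdr import train

        patches = self.separable_patches(40, seed=5)
        rng = np.random.default_rng(1)
        order = rng.permutation(len(patches))
        tr = [patches[i] for i in order[:120]]
        va = [patches[i] for i in order[120:]]
        # the fixture is separable by construction: a nearest-mean oracle is perfect
        assert self.nearest_mean_oracle(tr, va) == 1.0
        cfg = NetworkConfig(input_side=24)
        model = build_network(cfg, seed=1)
        history = train(model, tr, va, TrainingConfig(max_epochs=10, seed=1))
        assert history.val_accuracy.iloc[-1] >= 0.9

    def test_zero_learning_rate_is_noop(self):
        from fundusdr import train

        patches = self.separable_patches(4, seed=2)
        model = build_network(NetworkConfig(input_side=24), seed=0)
        before = {
            name: layer.params[key].copy()
            for name, layer, key in model.parameters()
        }
        cfg = TrainingConfig(learning_rate=0.0, weight_decay=0.0, max_epochs=2, seed=0)
        train(model, patches, patches, cfg)
        for name, layer, key in model.parameters():
            assert np.array_equal(before[name], layer.params[key]), name

    def test_same_seed_same_history(self):
        from fundusdr import train

        patches = self.separable_patches(6, seed=3)
        histories = []
        for _ in range(2):
            model = build_network(NetworkConfig(input_side=24), seed=7)
            histories.append(
                train(model, patches, patches, TrainingConfig(max_epochs=3, seed=7))
            )
        assert np.array_equal(
            histories[0].train_loss.values, histories[1].train_loss.values
        )

    def test_lr_step_down_schedule(self):
        cfg = TrainingConfig(learning_rate=0.01, lr_gamma=0.1, step_size=33)
        assert cfg.lr_at_epoch(0) == pytest.approx(0.01)
        assert cfg.lr_at_epoch(32) == pytest.approx(0.01)
        assert cfg.lr_at_epoch(33) == pytest.approx(0.001)
        assert cfg.lr_at_epoch(66) == pytest.approx(0.0001)

    def test_empty_split_rejected(self):
        from fundusdr import train

        model = build_network(NetworkConfig(input_side=24), seed=0)
        with pytest.raises(InvalidInputError):
            train(model, [], self.separable_patches(2), TrainingConfig())
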