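"""CNN shape contract, gradients, training and prediction."""

import numpy as np
import pytest

from netimg.classifier import (
    CNNSpec,
    TrainConfig,
    build_model,
    load_model,
    predict,
    save_model,
    shape_chain,
    train,
)
from netimg.imaging import NetworkImage


def separable_images(n_per_class=12, side=24, seed=0):
    """Two classes with disjoint bright quadrants: separable by construction."""
    rng = np.random.default_rng(seed)
    images = []
    for label, (r0, c0) in (("up", (0, 0)), ("down", (side // 2, side // 2))):
        for i in range(n_per_class):
            px = rng.uniform(0, 0.1, (side, side))
            px[r0 : r0 + side // 2, c0 : c0 + side // 2] += 0.8
            images.append(NetworkImage(f"{label}{i}", np.clip(px, 0, 1), label))
    return images


class TestShapeContract:
    def test_grid100_reproduces_printed_11x11x64(self):
        spec = CNNSpec(grid_size=100)
        assert shape_chain(spec) == [(96, 48), (46, 23), (21, 11)]
        model = build_model(spec)
        assert model.flat_size == 11 * 11 * 64 == 7744

    def test_floor_mode_breaks_the_contract(self):
        chain = shape_chain(CNNSpec(grid_size=100, pool_mode="floor"))
        assert chain[-1][1] == 10  # not the printed 11

    def test_grid32_shape_recurrence(self):
        # conv side = s - k + 1, pool side = ceil(s' / 2)
        spec = CNNSpec(grid_size=32)
        assert shape_chain(spec) == [(28, 14), (12, 6), (4, 2)]
        assert build_model(spec).flat_size == 2 * 2 * 64 == 256

    def test_output_width_follows_classes(self):
        model = build_model(CNNSpec(grid_size=100, n_classes=12))
        assert model.layers[-1].n_out == 12

    def test_too_small_grid_names_failing_stage(self):
        with pytest.raises(ValueError, match="stage 3"):
            shape_chain(CNNSpec(grid_size=16))

    def test_forward_shapes_match_chain(self):
        spec = CNNSpec(grid_size=32, n_classes=3)
        model = build_model(spec)
        model.initialize(np.random.default_rng(0))
        x = np.random.default_rng(1).uniform(size=(2, 1, 32, 32))
        out = model.logits(x)
        assert out.shape == (2, 3)


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        """Finite-difference check through conv, pool, ReLU and dense layers."""
        spec = CNNSpec(
            grid_size=7, conv_kernels=((3, 3, 3),), hidden=(6,), n_classes=3
        )
        model = build_model(spec)
        model.initialize(np.random.default_rng(2))
        rng = np.random.default_rng(3)
        x = rng.uniform(0.05, 1, size=(4, 1, 7, 7))
        y = np.array([0, 1, 2, 1])

        def loss():
            logits = model.logits(x, train=True)
            z = logits - logits.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            return -logp[np.arange(4), y].mean()

        base = loss()
        probs = np.exp(
            model.logits(x, train=True)
            - model.logits(x, train=True).max(axis=1, keepdims=True)
        )
        probs /= probs.sum(axis=1, keepdims=True)
        grad = probs.copy()
        grad[np.arange(4), y] -= 1
        grad /= 4
        loss()  # populate caches
        model.backward(grad)

        eps = 1e-6
        for layer in model.layers:
            for name, owner in layer.params():
                param = getattr(owner, name)
                analytic = getattr(owner, "d" + name)
                flat = param.ravel()
                picks = np.random.default_rng(4).choice(
                    flat.size, min(5, flat.size), replace=False
                )
                for idx in picks:
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up = loss()
                    flat[idx] = orig - eps
                    down = loss()
                    flat[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    assert analytic.ravel()[idx] == pytest.approx(numeric, abs=1e-4)


class TestTraining:
    def test_separable_fixture_learned(self):
        images = separable_images()
        model = build_model(CNNSpec(grid_size=24, n_classes=2, hidden=(32, 16)))
        model, curves = train(model, images, TrainConfig(epochs=10, seed=0))
        assert len(curves["train_accuracy"]) == 10
        assert curves["train_accuracy"][-1] >= 0.95
        # training images map back to their own class
        _, labels = predict(model, images)
        acc = np.mean([l == img.label for l, img in zip(labels, images)])
        assert acc >= 0.95

    def test_same_seed_identical_curves(self):
        images = separable_images()
        cfg = TrainConfig(epochs=3, seed=42)
        _, c1 = train(build_model(CNNSpec(grid_size=24, n_classes=2, hidden=(16,))), images, cfg)
        _, c2 = train(build_model(CNNSpec(grid_size=24, n_classes=2, hidden=(16,))), images, cfg)
        assert c1 == c2

    def test_permuted_labels_give_chance_level(self):
        rng = np.random.default_rng(8)
        images = separable_images(n_per_class=24, seed=8)
        labels = [img.label for img in images]
        rng.shuffle(labels)
        shuffled = [
            NetworkImage(img.sample_id, img.pixels, lab)
            for img, lab in zip(images, labels)
        ]
        model = build_model(CNNSpec(grid_size=24, n_classes=2, hidden=(16,)))
        _, curves = train(model, shuffled, TrainConfig(epochs=5, seed=8))
        assert abs(curves["test_accuracy"][-1] - 0.5) <= 0.15

    def test_single_class_rejected(self):
        images = [img for img in separable_images() if img.label == "up"]
        model = build_model(CNNSpec(grid_size=24, n_classes=2))
        with pytest.raises(ValueError, match="2 classes"):
            train(model, images, TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def fitted():
    images = separable_images()
    model = build_model(CNNSpec(grid_size=24, n_classes=2, hidden=(16,)))
    model, _ = train(model, images, TrainConfig(epochs=5, seed=1))
    return model, images


class TestPredict:
    def test_probabilities_sum_to_one(self, fitted):
        model, images = fitted
        probs, _ = predict(model, images)
        assert (probs >= 0).all()
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-5

    def test_batch_vs_single_identical(self, fitted):
        model, images = fitted
        _, batch_labels = predict(model, images)
        single = [predict(model, [img])[1][0] for img in images]
        assert batch_labels == single

    def test_untrained_model_rejected(self):
        model = build_model(CNNSpec(grid_size=24, n_classes=2))
        with pytest.raises(ValueError, match="not trained"):
            predict(model, separable_images(n_per_class=1))

    def test_shape_mismatch_rejected(self, fitted):
        model, _ = fitted
        bad = [NetworkImage("x", np.zeros((10, 10)), "up")]
        with pytest.raises(ValueError, match="grid size"):
            predict(model, bad)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        model, images = fitted
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        p1, l1 = predict(model, images)
        p2, l2 = predict(back, images)
        assert np.allclose(p1, p2)
        assert l1 == l2
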