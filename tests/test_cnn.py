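"""CNN architecture introspection, loss, gradients and training contracts."""

import numpy as np
import pytest
from scipy.special import expit

from emglesion.cnn import (
    ArchitectureSpec,
    CNNModel,
    LayerSpec,
    TrainingConfig,
    bc_loss,
    count_parameters,
    default_architecture,
    derive_shapes,
    predict,
    train,
)
from emglesion.preprocessing import SegmentDataset

# Published architecture table: (layer kind, temporal length, channels, params)
REFERENCE_ROWS = [
    ("conv1d", 500, 32, 192),
    ("maxpool1d", 250, 32, 0),
    ("conv1d", 125, 32, 5152),
    ("maxpool1d", 63, 32, 0),
    ("conv1d", 63, 64, 6208),
    ("maxpool1d", 32, 64, 0),
    ("dropout", 32, 64, 0),
    ("conv1d", 32, 128, 24704),
    ("maxpool1d", 16, 128, 0),
    ("dropout", 16, 128, 0),
    ("gap", 1, 128, 0),
    ("dense", 1, 100, 12900),
    ("dense", 1, 1, 101),
]


class TestArchitecture:
    def test_structure(self):
        spec = default_architecture()
        kinds = [l.kind for l in spec.layers]
        assert kinds.count("conv1d") == 4
        dropouts = [l.rate for l in spec.layers if l.kind == "dropout"]
        assert dropouts == [0.1, 0.1]
        assert spec.layers[-1].kind == "sigmoid"
        assert spec.layers[-2] == LayerSpec("dense", units=1)

    def test_shapes_match_reference_table(self):
        spec = default_architecture()
        shapes = derive_shapes(spec)
        got = [
            (l.kind, *shapes[i])
            for i, l in enumerate(spec.layers)
            if l.kind in ("conv1d", "maxpool1d", "dropout", "gap", "dense")
        ]
        # gap/dense report (1, width); compare (kind, length, channels)
        expected = [(k, ln, ch) for (k, ln, ch, _p) in REFERENCE_ROWS]
        assert [(k, a, b) for (k, a, b) in got] == expected

    def test_parameter_counts_match_reference_table(self):
        spec = default_architecture()
        counts, total = count_parameters(spec)
        per_layer = [
            counts[i]
            for i, l in enumerate(spec.layers)
            if l.kind in ("conv1d", "maxpool1d", "dropout", "gap", "dense")
        ]
        assert per_layer == [p for (*_x, p) in REFERENCE_ROWS]
        assert total == 49257

    def test_stride1_same_padding_preserves_length(self):
        spec = ArchitectureSpec(
            layers=(LayerSpec("conv1d", filters=8, kernel=3, stride=1),),
            input_length=63,
        )
        assert derive_shapes(spec)[0] == (63, 8)

    def test_model_parameter_arrays_match_count(self):
        spec = default_architecture()
        model = CNNModel(spec, seed=0)
        assert sum(p.size for p in model.params) == 49257

    def test_invalid_layer_kind(self):
        with pytest.raises(ValueError):
            derive_shapes(ArchitectureSpec(layers=(LayerSpec("blur"),)))


class TestBcLoss:
    def test_perfect_prediction(self):
        assert bc_loss([1 - 1e-7], [1.0]) < 1e-6

    def test_half_probability(self):
        assert bc_loss([0.5], [1.0]) == pytest.approx(np.log(2), abs=1e-9)

    def test_two_instances(self):
        assert bc_loss([0.8, 0.2], [1.0, 0.0]) == pytest.approx(
            -np.log(0.8), abs=1e-9
        )

    def test_matches_elementwise_bruteforce(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1e-6, 1 - 1e-6, size=100)
        x = rng.integers(0, 2, size=100).astype(float)
        yc = np.clip(y, 1e-7, 1 - 1e-7)
        brute = -sum(
            xi * np.log(yi) + (1 - xi) * np.log(1 - yi) for xi, yi in zip(x, yc)
        ) / len(x)
        assert bc_loss(y, x) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bc_loss([0.5, 0.5], [1.0])


def test_gradients_match_numerical_differences():
    """Analytic backprop vs central differences on a small all-layer net.

    Biases are randomized after init so no pre-activation sits exactly on a
    ReLU kink (where the two-sided difference and the subgradient rightly
    disagree).
    """
    layers = (
        LayerSpec("conv1d", filters=3, kernel=3, stride=2),
        LayerSpec("relu"),
        LayerSpec("maxpool1d", kernel=2, stride=2),
        LayerSpec("conv1d", filters=4, kernel=3, stride=1),
        LayerSpec("relu"),
        LayerSpec("gap"),
        LayerSpec("dense", units=5),
        LayerSpec("relu"),
        LayerSpec("dense", units=1),
        LayerSpec("sigmoid"),
    )
    spec = ArchitectureSpec(layers=layers, input_length=20)
    model = CNNModel(spec, seed=3)
    rng = np.random.default_rng(0)
    for p in model.params:
        if p.ndim == 1:  # bias
            p[...] = rng.normal(0.1, 0.05, size=p.shape)
    x = rng.random((4, 20))
    t = np.array([0.0, 1.0, 1.0, 0.0])

    def loss():
        return bc_loss(expit(model.forward_logits(x)), t)

    p_hat = expit(model.forward_logits(x))
    model.backward((p_hat - t) / len(t))
    analytic = [g.copy() for g in model.grads]

    eps = 1e-6
    for param, grad in zip(model.params, analytic):
        flat, gflat = param.reshape(-1), grad.reshape(-1)
        for j in range(0, flat.size, max(1, flat.size // 10)):
            orig = flat[j]
            flat[j] = orig + eps
            lp = loss()
            flat[j] = orig - eps
            lm = loss()
            flat[j] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(gflat[j], rel=1e-4, abs=1e-9)


def _separable_segments(n_per_class, length=1000, seed=0):
    """Class 0: slow ramp + noise; class 1: fast oscillation + noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    segs, labels = [], []
    for i in range(2 * n_per_class):
        label = i % 2
        if label:
            x = np.sin(2 * np.pi * 40 * t / length) + 0.1 * rng.normal(size=length)
        else:
            x = 0.1 * rng.normal(size=length)
        x = (x - x.min()) / (x.max() - x.min())
        segs.append(x)
        labels.append(label)
    return SegmentDataset(np.array(segs), np.array(labels), length)


class TestTraining:
    def test_history_schema_one_epoch(self):
        ds = _separable_segments(8)
        cfg = TrainingConfig(epochs=1, batch_size=8, seed=0)
        _, hist = train(default_architecture(), ds, ds, cfg)
        assert len(hist.train_loss) == len(hist.test_loss) == 1
        assert len(hist.train_acc) == len(hist.test_acc) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_decreases_on_separable_data(self, seed):
        ds = _separable_segments(16, seed=seed)
        cfg = TrainingConfig(epochs=8, batch_size=16, seed=seed)
        _, hist = train(default_architecture(), ds, ds, cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_same_seed_same_final_losses(self):
        ds = _separable_segments(8)
        cfg = TrainingConfig(epochs=2, batch_size=8, seed=5)
        _, h1 = train(default_architecture(), ds, ds, cfg)
        _, h2 = train(default_architecture(), ds, ds, cfg)
        assert abs(h1.train_loss[-1] - h2.train_loss[-1]) < 1e-6
        assert abs(h1.test_loss[-1] - h2.test_loss[-1]) < 1e-6

    def test_rejects_empty_and_nonbinary(self):
        ds = _separable_segments(4)
        empty = SegmentDataset(np.empty((0, 1000)), np.empty(0, dtype=int), 1000)
        with pytest.raises(ValueError):
            train(default_architecture(), empty, ds, TrainingConfig(epochs=1))
        bad = SegmentDataset(ds.segments, ds.labels + 1, 1000)
        with pytest.raises(ValueError):
            train(default_architecture(), bad, ds, TrainingConfig(epochs=1))


class TestPredict:
    def test_threshold_rule(self):
        # monkeypatch-free check of the rule itself on a trained tiny model
        ds = _separable_segments(4)
        model, _ = train(
            default_architecture(), ds, ds, TrainingConfig(epochs=1, batch_size=8)
        )
        probs, labels = predict(model, ds.segments)
        assert ((probs > 0.5) == labels.astype(bool)).all()
        assert set(np.unique(labels)) <= {0, 1}

    def test_wrong_length_rejected(self):
        ds = _separable_segments(4)
        model, _ = train(
            default_architecture(), ds, ds, TrainingConfig(epochs=1, batch_size=8)
        )
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 999)))


def test_model_save_load_roundtrip(tmp_path):
    ds = _separable_segments(4)
    model, _ = train(
        default_architecture(), ds, ds, TrainingConfig(epochs=1, batch_size=8)
    )
    path = tmp_path / "model.npz"
    model.save(path)
    back = CNNModel.load(path)
    np.testing.assert_allclose(
        back.predict_proba(ds.segments), model.predict_proba(ds.segments), rtol=1e-12
    )
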