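"""CNN architecture, dataset splitting, training mechanics, evaluation."""

import numpy as np
import pytest

from pdspeech import _nn
from pdspeech.classifier import (
    ConfusionCounts,
    TrainConfig,
    accuracy_from_counts,
    build_model,
    evaluate,
    split_dataset,
    train,
)

# canonical spatial-dimension sequence of the depthwise-separable stack:
# 224 -> 112 -> 56 -> 28 -> 14 -> 7 across the five stride-2 stages
EXPECTED_SPATIAL = [224] + [112] * 3 + [56] * 4 + [28] * 4 + [14] * 12 + [7] * 3


def test_layer_plan_spatial_dims():
    model = build_model(224, width_multiplier=1.0)
    conv_plan = [p for p in model.plan if p["kind"] in ("conv", "dw", "pw")]
    assert [p["in_spatial"] for p in conv_plan] == EXPECTED_SPATIAL
    assert conv_plan[-1]["out_spatial"] == 7
    assert conv_plan[-1]["channels"] == 1024
    assert model.plan[-1]["channels"] == 2  # binary head


def test_width_multiplier_quarters_channels():
    full = build_model(224, 1.0)
    quarter = build_model(224, 0.25)
    full_ch = [p["channels"] for p in full.plan if p["kind"] in ("conv", "pw")]
    quarter_ch = [p["channels"] for p in quarter.plan if p["kind"] in ("conv", "pw")]
    assert quarter_ch == [max(c // 4, 1) for c in full_ch]
    assert len(full.plan) == len(quarter.plan)


def test_forward_pass_probabilities():
    model = build_model(32, 0.1, seed=0)
    x = np.random.default_rng(0).random((2, 3, 32, 32)).astype(np.float32)
    probs = model.predict_proba(x)
    assert probs.shape == (2, 2)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_build_model_rejects_bad_input_size():
    with pytest.raises(ValueError):
        build_model(100)


def test_gradients_match_finite_differences(rng):
    """Backprop through conv/dw/bn/pool/dense agrees with central differences."""
    layers = [
        _nn.Conv2D(2, 3, 3, 2, rng),
        _nn.BatchNorm2D(3),
        _nn.ReLU(),
        _nn.DepthwiseConv2D(3, 3, 1, rng),
        _nn.Conv2D(3, 4, 1, 1, rng),
        _nn.GlobalAvgPool(),
        _nn.Dense(4, 2, rng),
    ]
    net = _nn.Sequential(layers)
    x = rng.standard_normal((4, 2, 8, 8))
    y = np.array([0, 1, 0, 1])

    def loss_fn():
        return _nn.softmax_cross_entropy(net.forward(x, train=True), y)[0]

    loss, grad = _nn.softmax_cross_entropy(net.forward(x, train=True), y)
    net.backward(grad)
    checked = 0
    for p, g in zip(net.params, net.grads):
        flat, gflat = p.ravel(), g.ravel()
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            eps = 1e-3  # float32 forward pass limits finite-difference precision
            old = flat[idx]
            flat[idx] = old + eps
            lp = loss_fn()
            flat[idx] = old - eps
            lm = loss_fn()
            flat[idx] = old
            numeric = (lp - lm) / (2 * eps)
            if abs(numeric) > 1e-4:
                assert g.ravel()[idx] == pytest.approx(numeric, rel=0.1, abs=1e-4)
                checked += 1
    assert checked > 10


def test_split_arithmetic_and_stratification():
    items = [(f"a{i}.jpg", "PD") for i in range(60)] + [(f"b{i}.jpg", "HC") for i in range(40)]
    split = split_dataset(items, seed=0)
    assert len(split.test) == 20
    assert len(split.validation) == 16
    assert len(split.train) == 64
    test_pd = sum(1 for _, lab in split.test if lab == "PD")
    assert test_pd == 12  # stratified 60/40
    # disjoint and exhaustive
    all_items = split.train + split.validation + split.test
    assert len(all_items) == 100
    assert len({path for path, _ in all_items}) == 100


def test_split_seed_reproducible():
    items = [(f"x{i}.jpg", "PD" if i % 3 else "HC") for i in range(50)]
    s1 = split_dataset(items, seed=7)
    s2 = split_dataset(items, seed=7)
    assert s1 == s2
    s3 = split_dataset(items, seed=8)
    assert s3 != s1


def test_split_subject_grouped():
    items, subjects = [], []
    for s in range(10):
        for i in range(8):
            items.append((f"s{s}_{i}.jpg", "PD" if s < 5 else "HC"))
            subjects.append(f"s{s}")
    split = split_dataset(items, seed=0, subjects=subjects)
    part_of = {}
    for name, part in (("train", split.train), ("val", split.validation), ("test", split.test)):
        for path, _ in part:
            subj = path.split("_")[0]
            assert part_of.setdefault(subj, name) == name, f"{subj} spans partitions"


def test_split_requires_both_classes():
    with pytest.raises(ValueError):
        split_dataset([("a.jpg", "PD")] * 10)


def test_accuracy_from_counts_closed_form_and_oracle(rng):
    assert accuracy_from_counts(ConfusionCounts(9, 9, 1, 1)) == pytest.approx(0.9)
    assert accuracy_from_counts(ConfusionCounts(10, 10, 0, 0)) == 1.0
    for _ in range(50):
        y_true = rng.integers(0, 2, 30)
        y_pred = rng.integers(0, 2, 30)
        tp = int(np.sum((y_pred == 1) & (y_true == 1)))
        tn = int(np.sum((y_pred == 0) & (y_true == 0)))
        fp = int(np.sum((y_pred == 1) & (y_true == 0)))
        fn = int(np.sum((y_pred == 0) & (y_true == 1)))
        direct = float(np.mean(y_pred == y_true))
        assert accuracy_from_counts(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(direct)


def _tiny_image_set(tmp_path, n_per_class=2, size=32):
    """Bright PD-ish vs dark HC-ish constant images."""
    from PIL import Image

    items = []
    for lab, level in (("PD", 180), ("HC", 60)):
        for i in range(n_per_class):
            texture = np.random.default_rng(i).integers(-40, 40, (size, size, 3))
            arr = np.clip(np.full((size, size, 3), level) + texture, 0, 255).astype(np.uint8)
            path = tmp_path / f"{lab}_{i}.jpg"
            Image.fromarray(arr).save(path, format="JPEG")
            items.append((str(path), lab))
    return items


def test_degenerate_training_reduces_loss(tmp_path):
    """Two-image memorization: training loss decreases over five epochs."""
    items = _tiny_image_set(tmp_path, n_per_class=1)
    from pdspeech.classifier import DatasetSplit

    split = DatasetSplit(train=items, validation=[], test=items)
    config = TrainConfig(epochs=5, input_size=32, width_multiplier=0.1, augment=False, seed=0)
    model = build_model(32, 0.1, seed=0)
    history = train(model, split, config)
    assert history["train_loss"][-1] < history["train_loss"][0]


def test_training_is_seeded_and_augmentation_changes_weights(tmp_path):
    items = _tiny_image_set(tmp_path, n_per_class=3)
    from pdspeech.classifier import DatasetSplit

    split = DatasetSplit(train=items, validation=[], test=items)

    def run(augment, seed=0):
        config = TrainConfig(
            epochs=2, input_size=32, width_multiplier=0.1, augment=augment, seed=seed
        )
        model = build_model(32, 0.1, seed=seed)
        train(model, split, config)
        return [p.copy() for p in model.net.params]

    w_plain_a = run(False)
    w_plain_b = run(False)
    for a, b in zip(w_plain_a, w_plain_b):
        np.testing.assert_array_equal(a, b)
    w_aug = run(True)
    assert any(not np.array_equal(a, b) for a, b in zip(w_plain_a, w_aug))


def test_evaluate_counts_and_perfect_predictor(tmp_path):
    items = _tiny_image_set(tmp_path, n_per_class=4)
    from pdspeech.classifier import DatasetSplit

    split = DatasetSplit(train=items, validation=[], test=items)
    config = TrainConfig(epochs=25, input_size=32, width_multiplier=0.1, augment=False, seed=1)
    model = build_model(32, 0.1, seed=1)
    train(model, split, config)
    result = evaluate(model, items)
    assert result.counts.total == len(items)
    if result.accuracy == 1.0:
        assert result.counts.fp == result.counts.fn == 0
    with pytest.raises(ValueError):
        evaluate(model, [])
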