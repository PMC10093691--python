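"""Classifier heads: routing, architecture/freeze policy, augmentation, training."""

import numpy as np
import pytest

from cnvnet import heads, nn
from cnvnet.augment import AffineParams, AugmentConfig, apply_affine
from cnvnet.exceptions import ParameterError, ValidationError
from cnvnet.imgio import FEATURES


def vgg16_oracle_total() -> int:
    """Independent parameter walk of the canonical 16-weight-layer VGG."""
    widths = [64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512]
    total, c_in = 0, 3
    for w in widths:
        total += 3 * 3 * c_in * w + w
        c_in = w
    total += 25088 * 4096 + 4096
    total += 4096 * 4096 + 4096
    total += 4096 * 1000 + 1000
    return total


def fc_head_oracle_total() -> int:
    return 513 * 419 + 420 * 1012 + 1013


# ---------------------------------------------------------------------------
# routing & preprocessing


def test_route_input_table(rng):
    roi = rng.random((32, 32))
    pa = (rng.random((32, 32)) > 0.5).astype(np.uint8)
    dh = (rng.random((32, 32)) > 0.5).astype(np.uint8)
    for feature in ("branch", "shape", "anastomosis_loops"):
        assert heads.route_input(feature, roi, pa, dh) is roi
    assert heads.route_input("peripheral_arcade", roi, pa, dh) is pa
    assert heads.route_input("dark_halo", roi, pa, dh) is dh
    with pytest.raises(ParameterError):
        heads.route_input("unknown", roi, pa, dh)
    with pytest.raises(ValidationError):
        heads.route_input("branch", roi, pa[:16], dh)


def test_preprocess_transfer_shape_and_replication(rng):
    checker = np.indices((448, 448)).sum(axis=0) % 2
    out = heads.preprocess_transfer(checker.astype(np.float32))
    assert out.shape == (224, 224, 3)
    const = heads.preprocess_transfer(np.full((224, 224), 0.5, dtype=np.float32))
    # identity resize, channels replicated then normalized per channel
    for c in range(3):
        expected = (0.5 - heads.IMAGENET_MEAN[c]) / heads.IMAGENET_STD[c]
        assert const[..., c] == pytest.approx(np.full((224, 224), expected), abs=1e-6)
    with pytest.raises(ValidationError):
        heads.preprocess_transfer(np.zeros((0, 0)))


# ---------------------------------------------------------------------------
# architectures & freeze policy


def test_classifier_table_reproduces_configuration_rows():
    table = heads.classifier_table()
    assert set(table) == set(FEATURES)
    assert table["branch"].trained_layers == "FC + Sigmoid"
    assert table["shape"].trained_layers == "3Conv + FC + Sigmoid"
    assert table["anastomosis_loops"].trained_layers == "1Conv + FC + Sigmoid"
    assert table["peripheral_arcade"].trained_layers == "all"
    assert table["dark_halo"].trained_layers == "FC + Sigmoid"
    assert table["peripheral_arcade"].mode == "scratch"
    assert all(table[f].mode == "transfer" for f in FEATURES if f != "peripheral_arcade")
    assert table["branch"].input_descriptor == "cnv_roi"
    assert table["peripheral_arcade"].input_descriptor == "pa_mask"
    assert table["dark_halo"].input_descriptor == "dh_mask"


def test_fc_only_heads_train_exactly_641000_parameters():
    for feature in ("branch", "dark_halo"):
        spec, model = heads.build_transfer_head(feature)
        assert spec.trainable_parameter_count == fc_head_oracle_total() == 641_000
        assert nn.parameter_count(model) == 641_000


def test_vgg16_reference_count_is_138_million():
    count = heads.vgg16_reference_parameter_count()
    assert count == vgg16_oracle_total()
    assert round(count / 1e6) == 138


def test_shape_head_unfreezes_exactly_last_three_convs():
    _, model = heads.build_transfer_head("shape")
    convs = [l for l in model.layers if isinstance(l, nn.Conv2d)]
    trainable_flags = [all(p.trainable for p in c.parameters()) for c in convs]
    assert trainable_flags == [False] * 10 + [True] * 3
    _, model = heads.build_transfer_head("anastomosis_loops")
    convs = [l for l in model.layers if isinstance(l, nn.Conv2d)]
    flags = [all(p.trainable for p in c.parameters()) for c in convs]
    assert flags == [False] * 12 + [True]


def test_transfer_head_rejects_peripheral_arcade():
    with pytest.raises(ParameterError):
        heads.build_transfer_head("peripheral_arcade")


def test_scratch_net_fully_trainable_and_counted():
    spec, model = heads.build_scratch_net(128, seed=1)
    assert all(p.trainable for p in model.parameters())
    widths = heads.SCRATCH_WIDTHS
    total, c_in = 0, 1
    for w in widths:
        total += 9 * c_in * w + w
        c_in = w
    total += (128 // 16) ** 2 * widths[-1] * 1 + 1
    assert spec.trainable_parameter_count == total
    _, again = heads.build_scratch_net(128, seed=1)
    for a, b in zip(model.parameters(), again.parameters()):
        assert np.array_equal(a.value, b.value)


def test_malformed_backbone_weights_raise(tmp_path):
    bad = tmp_path / "weights.npz"
    np.savez(bad, conv0_W=np.zeros((2, 2)), conv0_b=np.zeros(2))
    with pytest.raises(OSError):
        heads.build_transfer_head("branch", weights_path=str(bad))


# ---------------------------------------------------------------------------
# augmentation


def test_augment_identity_and_label_passthrough(rng):
    img = rng.random((16, 16)).astype(np.float32)
    out, label = heads.augment(img, 1, AugmentConfig(), rng)
    assert np.array_equal(out, img)
    assert label == 1


def test_horizontal_flip_is_involution(rng):
    img = rng.random((17, 17)).astype(np.float32)
    flip = AffineParams(flip_h=True)
    once = apply_affine(img, flip)
    twice = apply_affine(once, flip)
    np.testing.assert_allclose(twice, img, atol=1e-5)
    np.testing.assert_allclose(once, img[:, ::-1], atol=1e-5)


def test_quarter_rotation_moves_delta_pixel_to_analytic_position():
    img = np.zeros((21, 21), dtype=np.float32)
    img[4, 10] = 1.0  # 6 px above centre
    out = apply_affine(img, AffineParams(angle_deg=90.0))
    # rotating the image by +90 deg maps content at angle theta to theta+90:
    # the analytic image-space target of (4, 10) about centre (10, 10)
    got = np.unravel_index(np.argmax(out), out.shape)
    assert out[got] == pytest.approx(1.0, abs=1e-4)
    assert got in {(10, 4), (10, 16)}
    # and the rotation is exactly a quarter turn: rotating back recovers the pixel
    back = apply_affine(out, AffineParams(angle_deg=-90.0))
    assert np.unravel_index(np.argmax(back), back.shape) == (4, 10)


def test_out_of_bound_augment_config_rejected(rng):
    with pytest.raises(ParameterError):
        heads.augment(np.zeros((8, 8)), 0, AugmentConfig(rotation_deg=40.0), rng)
    with pytest.raises(ParameterError):
        heads.augment(np.zeros((8, 8)), 0, AugmentConfig(zoom=(0.5, 1.0)), rng)
    with pytest.raises(ParameterError):
        heads.augment(np.zeros((8, 8)), 0, AugmentConfig(shear_deg=15.0), rng)


# ---------------------------------------------------------------------------
# training & prediction


def test_training_leaves_frozen_backbone_bit_identical(rng):
    spec, model = heads.build_transfer_head("dark_halo", seed=0)
    frozen_before = [p.value.copy() for p in model.parameters() if not p.trainable]
    samples = [(heads.to_nchw(heads.preprocess_transfer(rng.random((64, 64)), 64)), i % 2)
               for i in range(4)]
    heads.train_head(model, samples, heads.HeadTrainConfig(epochs=1, seed=0))
    frozen_after = [p.value for p in model.parameters() if not p.trainable]
    assert all(np.array_equal(a, b) for a, b in zip(frozen_before, frozen_after))
    head_params = [p for p in model.parameters() if p.trainable]
    assert any(p.grad is not None for p in head_params)


def test_single_class_training_set_rejected(rng):
    _, model = heads.build_scratch_net(32, seed=0)
    samples = [(rng.random((1, 32, 32)).astype(np.float32), 1) for _ in range(4)]
    with pytest.raises(ValidationError):
        heads.train_head(model, samples)


def test_two_sample_memorization(rng):
    _, model = heads.build_scratch_net(32, seed=0)
    a = np.zeros((1, 32, 32), dtype=np.float32)
    b = np.ones((1, 32, 32), dtype=np.float32)
    samples = [(a, 0), (b, 1)]
    heads.train_head(model, samples, heads.HeadTrainConfig(lr=1e-3, epochs=60, batch_size=2, seed=0))
    preds = [heads.predict_feature(model, x, "peripheral_arcade").label for x, _ in samples]
    assert preds == [0, 1]


def test_prediction_threshold_rule(rng):
    # a model with all-zero weights emits logit 0 -> probability 0.5 -> label 1
    model = nn.Sequential([nn.Flatten(), nn.Dense(16, 1, rng)])
    model.parameters()[0].value[...] = 0.0
    model.parameters()[1].value[...] = 0.0
    pred = heads.predict_feature(model, np.ones((1, 4, 4), dtype=np.float32), "branch")
    assert pred.probability == pytest.approx(0.5)
    assert pred.label == 1
    model.parameters()[1].value[...] = -0.1  # probability just below 0.5
    pred = heads.predict_feature(model, np.ones((1, 4, 4), dtype=np.float32), "branch")
    assert pred.label == 0


def test_batch_labels_are_elementwise_threshold(rng):
    probs = rng.random(32)
    labels = (probs >= 0.5).astype(int)
    assert all(int(p >= 0.5) == l for p, l in zip(probs, labels))
    _, model = heads.build_scratch_net(32, seed=2)
    xs = [rng.random((1, 32, 32)).astype(np.float32) for _ in range(5)]
    preds = [heads.predict_feature(model, x, "peripheral_arcade") for x in xs]
    for p in preds:
        assert p.label == int(p.probability >= 0.5)
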