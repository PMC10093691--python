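"""Five binary activity-criterion classifiers.

Four criteria (branch, shape, anastomoses/loops, dark halo) use transfer
learning on a VGG16 convolutional backbone: the backbone is frozen except
for a designated suffix of convolutional layers, and a new fully connected
head (global average pool -> dense 419 -> dense 1012 -> dense 1 + sigmoid)
is trained. With the backbone fully frozen the trainable total is exactly
641,000 = 513*419 + 420*1012 + 1013. The peripheral-arcade criterion uses
a small network trained from scratch (4 conv+ReLU+pool blocks, one dense
layer, sigmoid), which outperformed transfer learning for that feature.

Input routing (criterion -> image):
  branch, shape, anastomosis_loops -> CNV ROI (mask x outer-retina en-face)
  peripheral_arcade               -> peripheral-arcade mask
  dark_halo                       -> dark-halo mask

Pretrained backbone weights are optional (a .npz path); with none given the
backbone is seeded-random with the identical architecture and freeze policy,
which is sufficient for every structural and training-mechanics guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .augment import AugmentConfig, AffineParams, apply_affine, sample_affine
from .exceptions import ParameterError, TrainingError, ValidationError
from .imgio import FEATURES

TRANSFER_FEATURES = ("branch", "shape", "anastomosis_loops", "dark_halo")

# Trained-layer policy per criterion (the classifier configuration table)
TRAINED_LAYERS = {
    "branch": "FC + Sigmoid",
    "shape": "3Conv + FC + Sigmoid",
    "anastomosis_loops": "1Conv + FC + Sigmoid",
    "peripheral_arcade": "All layers (4Conv + FC + Sigmoid)",
    "dark_halo": "FC + Sigmoid",
}
UNFROZEN_BACKBONE_CONVS = {"branch": 0, "shape": 3, "anastomosis_loops": 1, "dark_halo": 0}
INPUT_DESCRIPTOR = {
    "branch": "cnv_roi",
    "shape": "cnv_roi",
    "anastomosis_loops": "cnv_roi",
    "peripheral_arcade": "pa_mask",
    "dark_halo": "dh_mask",
}

# VGG16 convolutional plan: 13 conv layers (3x3) with 2x2 max pools
VGG16_CONV_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M"]
FC_HEAD_WIDTHS = (419, 1012)

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

TRANSFER_INPUT_SIZE = 224
SCRATCH_INPUT_SIZE = 128
SCRATCH_WIDTHS = (16, 32, 64, 128)


@dataclass(frozen=True)
class ClassifierSpec:
    feature: str
    mode: str  # 'transfer' | 'scratch'
    input_descriptor: str
    trained_layers: str
    trainable_parameter_count: int


@dataclass(frozen=True)
class FeaturePrediction:
    feature: str
    probability: float
    label: int


# ---------------------------------------------------------------------------
# input routing & preprocessing


def route_input(feature: str, roi: np.ndarray, pa_mask: np.ndarray, dh_mask: np.ndarray) -> np.ndarray:
    """Select the segmentation output each criterion's classifier consumes."""
    if feature not in FEATURES:
        raise ParameterError(f"unknown feature {feature!r}")
    if not (roi.shape == pa_mask.shape == dh_mask.shape):
        raise ValidationError("routing inputs must share the en-face grid shape")
    if feature in ("branch", "shape", "anastomosis_loops"):
        return roi
    if feature == "peripheral_arcade":
        return pa_mask
    return dh_mask


def preprocess_transfer(image: np.ndarray, out_size: int = TRANSFER_INPUT_SIZE) -> np.ndarray:
    """Bilinear resize to (out_size, out_size, 3) and normalize per channel."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValidationError("input must be a non-empty 2-D grid")
    if image.shape != (out_size, out_size):
        image = resize(image, (out_size, out_size), order=1, anti_aliasing=True, preserve_range=True)
    three = np.repeat(image[:, :, None], 3, axis=2).astype(np.float32)
    return (three - IMAGENET_MEAN) / IMAGENET_STD


def prepare_scratch(image: np.ndarray, input_size: int = SCRATCH_INPUT_SIZE) -> np.ndarray:
    """Resize a 2-D grid to the scratch net's (1, s, s) input."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValidationError("input must be a non-empty 2-D grid")
    if image.shape != (input_size, input_size):
        image = resize(image, (input_size, input_size), order=1, anti_aliasing=True, preserve_range=True)
    return image[None].astype(np.float32)


def to_nchw(image: np.ndarray) -> np.ndarray:
    """(H, W, C) channel-last -> (C, H, W); (C, H, W) passes through."""
    if image.ndim != 3:
        raise ValidationError("expected a 3-D array")
    if image.shape[2] in (1, 3) and image.shape[0] not in (1, 3):
        return np.ascontiguousarray(image.transpose(2, 0, 1))
    return image


# ---------------------------------------------------------------------------
# architectures


def _build_backbone(rng: np.random.Generator, weights_path: str | None = None
                    ) -> tuple[list[nn.Layer], list[nn.Conv2d]]:
    layers: list[nn.Layer] = []
    convs: list[nn.Conv2d] = []
    c_in = 3
    for k, item in enumerate(VGG16_CONV_PLAN):
        if item == "M":
            layers.append(nn.MaxPool2())
        else:
            conv = nn.Conv2d(c_in, int(item), 3, rng, name=f"vgg_conv{len(convs)}")
            layers.append(conv)
            layers.append(nn.ReLU())
            convs.append(conv)
            c_in = int(item)
    if weights_path is not None:
        try:
            data = np.load(weights_path)
            for i, conv in enumerate(convs):
                w, b = data[f"conv{i}_W"], data[f"conv{i}_b"]
                if w.shape != conv.weight.value.shape:
                    raise ValidationError(f"backbone weight shape mismatch at conv{i}")
                conv.weight.value[...] = w
                conv.bias.value[...] = b
        except (OSError, KeyError, ValidationError, ValueError) as exc:
            raise OSError(f"malformed backbone weights file {weights_path}: {exc}") from exc
    return layers, convs


def _fc_head(rng: np.random.Generator) -> list[nn.Layer]:
    d1, d2 = FC_HEAD_WIDTHS
    return [
        nn.GlobalAvgPool(),
        nn.Dense(512, d1, rng, name="head_fc1"), nn.ReLU(),
        nn.Dense(d1, d2, rng, name="head_fc2"), nn.ReLU(),
        nn.Dense(d2, 1, rng, name="head_out"),
    ]


def build_transfer_head(feature: str, seed: int = 0,
                        weights_path: str | None = None) -> tuple[ClassifierSpec, nn.Sequential]:
    """Transfer-learning classifier: VGG16 backbone + new FC head.

    The backbone is frozen except the last N convolutions given by the
    per-criterion policy; the FC head is always trainable. The model
    outputs a logit; apply a sigmoid (``predict_feature``) for the
    probability.
    """
    if feature == "peripheral_arcade":
        raise ParameterError("peripheral_arcade uses build_scratch_net, not transfer learning")
    if feature not in TRANSFER_FEATURES:
        raise ParameterError(f"unknown transfer feature {feature!r}")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 301])
    backbone, convs = _build_backbone(rng, weights_path)
    model = nn.Sequential(backbone + _fc_head(rng))
    for conv in convs:
        for p in conv.parameters():
            p.trainable = False
    n_unfrozen = UNFROZEN_BACKBONE_CONVS[feature]
    for conv in convs[len(convs) - n_unfrozen:]:
        for p in conv.parameters():
            p.trainable = True
    spec = ClassifierSpec(
        feature=feature,
        mode="transfer",
        input_descriptor=INPUT_DESCRIPTOR[feature],
        trained_layers=TRAINED_LAYERS[feature],
        trainable_parameter_count=nn.parameter_count(model),
    )
    return spec, model


def build_scratch_net(input_size: int = SCRATCH_INPUT_SIZE, seed: int = 0
                      ) -> tuple[ClassifierSpec, nn.Sequential]:
    """The from-scratch peripheral-arcade network: 4 conv blocks + dense + sigmoid."""
    if input_size <= 0:
        raise ParameterError("input_size must be positive")
    if input_size % 16:
        raise ParameterError("input_size must be divisible by 16 (four 2x2 pools)")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 302])
    layers: list[nn.Layer] = []
    c_in = 1
    for i, w in enumerate(SCRATCH_WIDTHS):
        layers += [nn.Conv2d(c_in, w, 3, rng, name=f"pa_conv{i}"), nn.ReLU(), nn.MaxPool2()]
        c_in = w
    feat = (input_size // 16) ** 2 * SCRATCH_WIDTHS[-1]
    layers += [nn.Flatten(), nn.Dense(feat, 1, rng, name="pa_out")]
    model = nn.Sequential(layers)
    spec = ClassifierSpec(
        feature="peripheral_arcade",
        mode="scratch",
        input_descriptor=INPUT_DESCRIPTOR["peripheral_arcade"],
        trained_layers="all",
        trainable_parameter_count=nn.parameter_count(model),
    )
    return spec, model


def classifier_table(input_size: int = SCRATCH_INPUT_SIZE) -> dict[str, ClassifierSpec]:
    """The five heads' (input, mode, trained layers) configuration, row by row."""
    table = {}
    for feature in FEATURES:
        if feature == "peripheral_arcade":
            table[feature] = build_scratch_net(input_size)[0]
        else:
            table[feature] = build_transfer_head(feature)[0]
    return table


def vgg16_reference_parameter_count() -> int:
    """Canonical VGG16 total (13 convs + 4096/4096/1000 classifier), closed form."""
    total = 0
    c_in = 3
    for item in VGG16_CONV_PLAN:
        if item == "M":
            continue
        total += 9 * c_in * int(item) + int(item)
        c_in = int(item)
    feat = 512 * 7 * 7  # 224 input after five pools
    for n_in, n_out in ((feat, 4096), (4096, 4096), (4096, 1000)):
        total += n_in * n_out + n_out
    return total


def fc_head_parameter_count() -> int:
    """Closed-form trainable total of the FC head (frozen-backbone configuration)."""
    d1, d2 = FC_HEAD_WIDTHS
    return 512 * d1 + d1 + d1 * d2 + d2 + d2 + 1


# ---------------------------------------------------------------------------
# augmentation (label-preserving by construction)


def augment(image: np.ndarray, label: int, aug_config: AugmentConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Random affine augmentation of one sample; the label passes through."""
    params = sample_affine(aug_config, rng)
    return apply_affine_multi(image, params), label


def apply_affine_multi(image: np.ndarray, params: AffineParams) -> np.ndarray:
    """Apply one affine transform to a 2-D grid or each channel of (C, H, W)."""
    if image.ndim == 2:
        return apply_affine(image, params, order=1)
    return np.stack([apply_affine(image[c], params, order=1) for c in range(image.shape[0])])


# ---------------------------------------------------------------------------
# training & prediction


@dataclass
class HeadTrainConfig:
    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    augment: AugmentConfig | None = None


def _first_trainable_index(model: nn.Sequential) -> int:
    for i, layer in enumerate(model.layers):
        if any(p.trainable for p in layer.parameters()):
            return i
    return len(model.layers)


def train_head(model: nn.Sequential, samples: list[tuple[np.ndarray, int]],
               config: HeadTrainConfig = HeadTrainConfig()) -> tuple[nn.Sequential, list[float]]:
    """Train one binary head with cross-entropy; returns per-epoch loss trace.

    Samples are (C, H, W) arrays already preprocessed for the head's mode.
    Both classes must be present. When the model has a frozen prefix and no
    augmentation is requested, the prefix activations are computed once and
    cached, so frozen layers are never re-evaluated (and never updated:
    their weights stay bit-identical through training).
    """
    if not samples:
        raise ValidationError("training set is empty")
    labels = np.array([int(y) for _, y in samples], dtype=np.float32)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("training set must contain both classes")
    x = np.stack([img for img, _ in samples]).astype(np.float32)
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 401])
    optimizer = nn.Adam(model.parameters(), lr=config.lr)

    split = _first_trainable_index(model)
    cache_prefix = split > 0 and config.augment is None
    if cache_prefix:
        prefix = nn.Sequential(model.layers[:split])
        feats = np.concatenate([prefix.forward(x[i : i + 4], train=False)
                                for i in range(0, len(x), 4)])
    else:
        feats = x
        split = 0 if config.augment is not None else split

    trace: list[float] = []
    n = len(samples)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = feats[idx]
            yb = labels[idx][:, None]
            if config.augment is not None:
                xb = np.stack([apply_affine_multi(xb[j], sample_affine(config.augment, rng))
                               for j in range(len(idx))])
            optimizer.zero_grad()
            h = xb
            for layer in model.layers[split:] if cache_prefix else model.layers:
                h = layer.forward(h, train=True)
            loss, grad = nn.bce_with_logits(h, yb)
            if not np.isfinite(loss):
                raise TrainingError("non-finite classification loss")
            if cache_prefix:
                model.backward_until(grad, split)
            else:
                model.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        trace.append(epoch_loss / n_batches)
    return model, trace


def predict_feature(model: nn.Sequential, image: np.ndarray, feature: str) -> FeaturePrediction:
    """Sigmoid probability and the >= 0.5 decision for one prepared input."""
    if feature not in FEATURES:
        raise ParameterError(f"unknown feature {feature!r}")
    if image.ndim != 3:
        raise ValidationError("expected a (C, H, W) prepared input")
    logit = model.forward(image[None].astype(np.float32), train=False)
    prob = float(nn.sigmoid(logit)[0, 0])
    return FeaturePrediction(feature=feature, probability=prob, label=int(prob >= 0.5))
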