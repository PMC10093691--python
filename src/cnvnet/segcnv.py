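"""SEG-CNV: a parameter-reduced U-Net for CNV lesion segmentation.

Encoder-decoder with skip connections: two 3x3 conv + ReLU per level,
2x2 max pooling down, nearest-neighbour upsampling followed by a 2x2
convolution up, dropout on the two deepest blocks, and a final 1x1
convolution + sigmoid producing one foreground probability per pixel.

The reference configuration for 128 x 128 grayscale input uses encoder
widths (16, 32, 64, 128) with a 192-channel bottleneck; its trainable
parameter total is 1,576,145 (~1.6 M), an order of magnitude below the
~30 M of the classic U-Net, which is the point: small datasets overfit
the full-size model. Training minimises the soft Dice loss
1 - (2|CNV∩GT| + eps) / (|CNV| + |GT| + eps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .augment import AugmentConfig, apply_affine, sample_affine
from .exceptions import ConfigurationError, TrainingError, ValidationError

REFERENCE_WIDTHS = (16, 32, 64, 128)
REFERENCE_BOTTLENECK = 192
DROPOUT_RATE = 0.2
PARAM_BAND = (1_550_000, 1_650_000)  # budget for the reference 128x128x1 build


@dataclass(frozen=True)
class SegModelSpec:
    input_height: int
    input_width: int
    input_channels: int
    encoder_widths: tuple[int, ...]
    bottleneck_width: int
    dropout_levels: tuple[str, ...]
    trainable_parameter_count: int


class UNet(nn.Layer):
    """U-Net with explicit skip handling on the numpy layer engine."""

    def __init__(self, height: int, width: int, widths: tuple[int, ...] = REFERENCE_WIDTHS,
                 bottleneck: int = REFERENCE_BOTTLENECK, dropout_rate: float = DROPOUT_RATE,
                 seed: int = 0):
        levels = len(widths)
        factor = 2**levels
        if height % factor or width % factor:
            raise ConfigurationError(f"input size must be divisible by {factor}")
        self.height, self.width = height, width
        self.widths = tuple(widths)
        self.bottleneck_width = bottleneck
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
        drop_rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 102])

        self.enc: list[nn.Sequential] = []
        self.pools: list[nn.MaxPool2] = []
        c_in = 1
        for i, w in enumerate(widths):
            layers: list[nn.Layer] = [
                nn.Conv2d(c_in, w, 3, rng, name=f"enc{i}a"), nn.ReLU(),
                nn.Conv2d(w, w, 3, rng, name=f"enc{i}b"), nn.ReLU(),
            ]
            if i == levels - 1:  # deepest encoder block carries dropout
                layers.append(nn.Dropout(dropout_rate, drop_rng))
            self.enc.append(nn.Sequential(layers))
            self.pools.append(nn.MaxPool2())
            c_in = w
        self.bottleneck = nn.Sequential([
            nn.Conv2d(widths[-1], bottleneck, 3, rng, name="bn_a"), nn.ReLU(),
            nn.Conv2d(bottleneck, bottleneck, 3, rng, name="bn_b"), nn.ReLU(),
            nn.Dropout(dropout_rate, drop_rng),
        ])
        self.ups: list[nn.UpsampleNearest2] = []
        self.upconvs: list[nn.Conv2d] = []
        self.dec: list[nn.Sequential] = []
        deeper = bottleneck
        for i in reversed(range(levels)):
            w = widths[i]
            self.ups.insert(0, nn.UpsampleNearest2())
            self.upconvs.insert(0, nn.Conv2d(deeper, w, 2, rng, name=f"up{i}"))
            self.dec.insert(0, nn.Sequential([
                nn.Conv2d(2 * w, w, 3, rng, name=f"dec{i}a"), nn.ReLU(),
                nn.Conv2d(w, w, 3, rng, name=f"dec{i}b"), nn.ReLU(),
            ]))
            deeper = w
        self.out_conv = nn.Conv2d(widths[0], 1, 1, rng, name="out")
        self.out_sig = nn.Sigmoid()

    def parameters(self) -> list[nn.Parameter]:
        params: list[nn.Parameter] = []
        for block in (*self.enc, self.bottleneck, *self.upconvs, *self.dec, self.out_conv):
            params.extend(block.parameters())
        return params

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for i in reversed(range(len(self.enc))):
            h = self.ups[i].forward(h, train)
            h = self.upconvs[i].forward(h, train)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec[i].forward(h, train)
        return self.out_sig.forward(self.out_conv.forward(h, train), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.out_conv.backward(self.out_sig.backward(grad))
        skip_grads: list[np.ndarray | None] = [None] * len(self.enc)
        for i in range(len(self.enc)):
            g = self.dec[i].backward(g)
            w = self.widths[i]
            skip_grads[i] = g[:, :w]
            g = self.ups[i].backward(self.upconvs[i].backward(g[:, w:]))
        g = self.bottleneck.backward(g)
        for i in reversed(range(len(self.enc))):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        return g


def build_segcnv(height: int, width: int, seed: int = 0,
                 widths: tuple[int, ...] = REFERENCE_WIDTHS,
                 bottleneck: int = REFERENCE_BOTTLENECK) -> tuple[SegModelSpec, UNet]:
    """Build the SEG-CNV model and report its trainable parameter count."""
    model = UNet(height, width, widths=widths, bottleneck=bottleneck, seed=seed)
    spec = SegModelSpec(
        input_height=height,
        input_width=width,
        input_channels=1,
        encoder_widths=tuple(widths),
        bottleneck_width=bottleneck,
        dropout_levels=("deepest_encoder", "bottleneck"),
        trainable_parameter_count=nn.parameter_count(model),
    )
    return spec, model


# ---------------------------------------------------------------------------
# Dice loss (scalar form on a single prediction/ground-truth pair)


def dice_loss(pred: np.ndarray, gt: np.ndarray, eps: float = nn.DICE_EPS) -> float:
    """Soft Dice loss 1 - (2 sum(p*g) + eps) / (sum(p) + sum(g) + eps)."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {gt.shape}")
    inter = float((pred * gt).sum())
    sums = float(pred.sum() + gt.sum())
    return 1.0 - (2.0 * inter + eps) / (sums + eps)


# ---------------------------------------------------------------------------
# training


@dataclass
class SegTrainConfig:
    lr: float = 3e-4
    batch_size: int = 8
    epochs: int = 50
    seed: int = 0
    augment: AugmentConfig | None = None


def _resize_image(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape == shape:
        return img.astype(np.float32)
    return resize(img.astype(np.float64), shape, order=1, anti_aliasing=True,
                  preserve_range=True).astype(np.float32)


def _resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mask.shape == shape:
        return (np.asarray(mask) > 0).astype(np.float32)
    out = resize(np.asarray(mask).astype(np.float64), shape, order=0,
                 anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.float32)


def train_segcnv(model: UNet, dataset: list[tuple[np.ndarray, np.ndarray]],
                 config: SegTrainConfig = SegTrainConfig()) -> tuple[UNet, list[float]]:
    """Train SEG-CNV with the soft Dice loss; returns the per-epoch loss trace.

    Images/masks are resized to the model grid. All stochastic stages
    (shuffling, augmentation sampling, dropout) flow from ``config.seed``.
    """
    if not dataset:
        raise ValidationError("training dataset is empty")
    shape = (model.height, model.width)
    images = np.stack([_resize_image(img, shape) for img, _ in dataset])[:, None]
    masks = np.stack([_resize_mask(m, shape) for _, m in dataset])[:, None]
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 201])
    optimizer = nn.Adam(model.parameters(), lr=config.lr)
    trace: list[float] = []
    n = len(dataset)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = images[idx], masks[idx]
            if config.augment is not None:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(idx)):
                    t = sample_affine(config.augment, rng)
                    xb[j, 0] = apply_affine(xb[j, 0], t, order=1)
                    yb[j, 0] = (apply_affine(yb[j, 0], t, order=0) > 0.5).astype(np.float32)
            optimizer.zero_grad()
            probs = model.forward(xb, train=True)
            loss, grad = nn.soft_dice_loss(probs, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite Dice loss at epoch {len(trace)}")
            model.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        trace.append(epoch_loss / n_batches)
    return model, trace


def predict_mask(model: UNet, enface: np.ndarray) -> np.ndarray:
    """Predict a binary CNV mask at the en-face's native resolution.

    Probabilities are thresholded at 0.5 with ties going to foreground;
    the mask is brought back to the input size by nearest neighbour.
    """
    enface = np.asarray(enface)
    if enface.ndim != 2 or enface.size == 0:
        raise ValidationError("enface must be a non-empty 2-D grid")
    x = _resize_image(enface, (model.height, model.width))[None, None]
    probs = model.forward(x, train=False)[0, 0]
    mask = threshold_probabilities(probs)
    if mask.shape != enface.shape:
        out = resize(mask.astype(np.float64), enface.shape, order=0,
                     anti_aliasing=False, preserve_range=True)
        mask = (out > 0.5).astype(np.uint8)
    return mask


def threshold_probabilities(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary decision rule: foreground iff probability >= threshold."""
    return (np.asarray(probs) >= threshold).astype(np.uint8)


def make_roi(enface: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """CNV region of interest: elementwise product of en-face and mask."""
    enface = np.asarray(enface)
    mask = np.asarray(mask)
    if enface.shape != mask.shape:
        raise ValidationError(f"shape mismatch {enface.shape} vs {mask.shape}")
    return (enface * (mask > 0)).astype(np.float32)


def evaluate_dice(model: UNet, dataset: list[tuple[np.ndarray, np.ndarray]]) -> list[float]:
    """Per-sample Dice coefficients of predicted vs ground-truth masks."""
    from .evalkit import dice_coefficient

    return [dice_coefficient(predict_mask(model, img), (np.asarray(m) > 0).astype(np.uint8))
            for img, m in dataset]


def grid_search_segcnv(
    train_set: list[tuple[np.ndarray, np.ndarray]],
    val_set: list[tuple[np.ndarray, np.ndarray]],
    input_size: int,
    lrs: tuple[float, ...] = (3e-4, 1e-4),
    batch_sizes: tuple[int, ...] = (4, 8),
    epochs: int = 10,
    seed: int = 0,
) -> tuple[dict, float]:
    """Small hyperparameter grid over learning rate x batch size.

    Returns the best {'lr','batch_size'} by mean validation Dice.
    """
    best: tuple[dict, float] = ({}, -1.0)
    for lr in lrs:
        for bs in batch_sizes:
            _, model = build_segcnv(input_size, input_size, seed=seed)
            cfg = SegTrainConfig(lr=lr, batch_size=bs, epochs=epochs, seed=seed)
            train_segcnv(model, train_set, cfg)
            score = float(np.mean(evaluate_dice(model, val_set)))
            if score > best[1]:
                best = ({"lr": lr, "batch_size": bs}, score)
    return best
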