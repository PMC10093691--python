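"""Affine data augmentation shared by the segmentation and classifier trainers.

Transforms are rotation, isotropic zoom, shear and axis flips, sampled from a
seeded generator and applied about the image centre. Labels are never touched
by augmentation; for segmentation the same geometric transform is applied to
the image (bilinear) and its mask (nearest neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError

# hard bounds on what counts as a label-preserving augmentation
MAX_ROTATION_DEG = 25.0
ZOOM_BOUNDS = (0.8, 1.2)
MAX_SHEAR_DEG = 10.0


@dataclass(frozen=True)
class AugmentConfig:
    """Sampling ranges for one random affine transform.

    rotation_deg: max |rotation| in degrees (uniform in [-r, r])
    zoom: (low, high) isotropic scale factor range
    flip_horizontal / flip_vertical: whether flips may be sampled (p=0.5 each)
    shear_deg: max |shear| in degrees
    """

    rotation_deg: float = 0.0
    zoom: tuple[float, float] = (1.0, 1.0)
    flip_horizontal: bool = False
    flip_vertical: bool = False
    shear_deg: float = 0.0

    def validate(self) -> None:
        if abs(self.rotation_deg) > MAX_ROTATION_DEG:
            raise ParameterError(f"rotation must be within +/-{MAX_ROTATION_DEG} degrees")
        lo, hi = self.zoom
        if lo > hi or lo < ZOOM_BOUNDS[0] or hi > ZOOM_BOUNDS[1]:
            raise ParameterError(f"zoom range must lie inside {ZOOM_BOUNDS}")
        if abs(self.shear_deg) > MAX_SHEAR_DEG:
            raise ParameterError(f"shear must be within +/-{MAX_SHEAR_DEG} degrees")


IDENTITY = AugmentConfig()


@dataclass(frozen=True)
class AffineParams:
    angle_deg: float = 0.0
    zoom: float = 1.0
    shear_deg: float = 0.0
    flip_h: bool = False
    flip_v: bool = False

    @property
    def is_identity(self) -> bool:
        return (
            self.angle_deg == 0.0
            and self.zoom == 1.0
            and self.shear_deg == 0.0
            and not self.flip_h
            and not self.flip_v
        )


def sample_affine(config: AugmentConfig, rng: np.random.Generator) -> AffineParams:
    config.validate()
    angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg)) if config.rotation_deg else 0.0
    lo, hi = config.zoom
    zoom = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    shear = float(rng.uniform(-config.shear_deg, config.shear_deg)) if config.shear_deg else 0.0
    flip_h = bool(rng.random() < 0.5) if config.flip_horizontal else False
    flip_v = bool(rng.random() < 0.5) if config.flip_vertical else False
    return AffineParams(angle, zoom, shear, flip_h, flip_v)


def _matrix(params: AffineParams) -> np.ndarray:
    a = np.deg2rad(params.angle_deg)
    s = np.deg2rad(params.shear_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    shear = np.array([[1.0, np.tan(s)], [0.0, 1.0]])
    flip = np.diag([-1.0 if params.flip_v else 1.0, -1.0 if params.flip_h else 1.0])
    return params.zoom * (rot @ shear @ flip)


def apply_affine(image: np.ndarray, params: AffineParams, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Apply the transform about the image centre. order=0 for masks."""
    if params.is_identity:
        return image.copy()
    fwd = _matrix(params)
    inv = np.linalg.inv(fwd)  # ndimage maps output coords -> input coords
    centre = (np.asarray(image.shape, dtype=np.float64) - 1.0) / 2.0
    offset = centre - inv @ centre
    out = ndimage.affine_transform(
        image.astype(np.float32), inv, offset=offset, order=order, mode="constant", cval=cval
    )
    return out.astype(np.float32)
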