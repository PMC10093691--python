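"""Classical segmentation of the peripheral arcade (SEG-PA) and dark halo (SEG-DH).

SEG-PA: binarize vessels around the lesion, invert within the (dilated)
lesion mask so inter-vessel spaces become foreground, then keep only the
band straddling the lesion boundary (ring mask). The result marks the open
spaces between vessels at the lesion margin, where a peripheral arcade
closes them off.

SEG-DH: enhance the choriocapillaris image with contrast-limited adaptive
histogram equalization, seed a region-growing pass from the lesion contour
(offset one pixel outward), and keep grown pixels inside a bounded search
annulus, excluding the lesion interior.

All operations are pure and deterministic. Parameters the study leaves
unnamed (binarization window/offset, structuring elements, ring thickness,
growing tolerance, CLAHE tiling) are exposed here with defaults tuned once
on phantoms and frozen; defaults are stated at a 304 x 304 grid and scale
proportionally with image size.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .exceptions import ParameterError, ValidationError

# defaults at the reference 304 x 304 grid
DEFAULT_WINDOW = 15
# negative offset tightens the vessel criterion to mean + |offset| * range,
# so granular background texture does not binarize as vessel
DEFAULT_OFFSET = -0.15
DEFAULT_RING_RADIUS = 5  # outward = inward = 5 px at 304
DEFAULT_TOLERANCE = 0.15
REFERENCE_SIZE = 304


def _scaled(px: int, shape: tuple[int, int]) -> int:
    return max(1, round(px * shape[0] / REFERENCE_SIZE))


def disk_footprint(radius: int) -> np.ndarray:
    """Disk structuring element of the given radius (Euclidean)."""
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    extent = 2 * radius + 1
    rr, cc = np.mgrid[:extent, :extent] - radius
    return (rr**2 + cc**2) <= radius**2


def square_footprint(radius: int) -> np.ndarray:
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def _footprint(radius: int, kind: str) -> np.ndarray:
    if kind == "disk":
        return disk_footprint(radius)
    if kind == "square":
        return square_footprint(radius)
    raise ParameterError(f"unknown footprint kind {kind!r}")


# ---------------------------------------------------------------------------
# primitives


def binarize_vessels(enface: np.ndarray, mask: np.ndarray, window: int = DEFAULT_WINDOW,
                     offset: float = DEFAULT_OFFSET) -> np.ndarray:
    """Local adaptive vessel binarization, evaluated inside ``mask`` only.

    A pixel is vessel iff its intensity strictly exceeds the local mean over
    ``window`` minus ``offset`` times the local intensity range (borders are
    reflected). Constant regions therefore binarize to zero.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError("window must be odd and >= 3")
    if enface.shape != mask.shape:
        raise ValidationError("enface and mask shapes differ")
    img = enface.astype(np.float64)
    local_mean = ndimage.uniform_filter(img, size=window, mode="reflect")
    local_max = ndimage.maximum_filter(img, size=window, mode="reflect")
    local_min = ndimage.minimum_filter(img, size=window, mode="reflect")
    threshold = local_mean - offset * (local_max - local_min)
    out = (img > threshold) & (np.asarray(mask) > 0)
    return out.astype(np.uint8)


def invert_within_mask(binary: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """1 - binary inside the mask, 0 outside it."""
    if binary.shape != mask.shape:
        raise ValidationError("binary and mask shapes differ")
    m = np.asarray(mask) > 0
    return (m & ~(np.asarray(binary) > 0)).astype(np.uint8)


def ring_mask(mask: np.ndarray, outward: int, inward: int = 0,
              footprint: str = "disk") -> np.ndarray:
    """Band straddling the mask boundary: dilate(outward) AND NOT erode(inward)."""
    if outward < 1:
        raise ParameterError("outward must be >= 1")
    if inward < 0:
        raise ParameterError("inward must be >= 0")
    m = np.asarray(mask) > 0
    dil = ndimage.binary_dilation(m, structure=_footprint(outward, footprint))
    ero = ndimage.binary_erosion(m, structure=_footprint(inward, footprint)) if inward > 0 else m
    return (dil & ~ero).astype(np.uint8)


def enhance_choroid(enface: np.ndarray, kernel_size: int | None = None,
                    clip_limit: float = 0.02) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, output in [0, 1].

    ``kernel_size`` defaults to an 8 x 8 tiling of the image. Constant
    images are returned unchanged.
    """
    img = np.clip(np.asarray(enface, dtype=np.float64), 0.0, 1.0)
    if img.max() - img.min() < 1e-12:
        return img.astype(np.float32)
    if kernel_size is None:
        kernel_size = max(8, img.shape[0] // 8)
    out = exposure.equalize_adapthist(img, kernel_size=kernel_size, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def region_grow(image: np.ndarray, seeds: list[tuple[int, int]] | np.ndarray,
                tolerance: float, connectivity: int = 4) -> np.ndarray:
    """Seeded region growing with a running-mean similarity criterion.

    Starts from the seed set (accepted unconditionally); a 4-connected
    neighbour is absorbed iff its intensity differs from the current region
    mean by at most ``tolerance``. The frontier is a FIFO queue with seeds
    sorted row-major and neighbours visited in row-major order, which makes
    the result deterministic.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    if connectivity != 4:
        raise ParameterError("only 4-connectivity is supported")
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    seed_list = sorted({(int(r), int(c)) for r, c in np.asarray(seeds).reshape(-1, 2)})
    if not seed_list:
        raise ValidationError("seed set is empty")
    for r, c in seed_list:
        if not (0 <= r < h and 0 <= c < w):
            raise ValidationError(f"seed {(r, c)} out of bounds")

    accepted = np.zeros((h, w), dtype=bool)
    total = 0.0
    count = 0
    queue: deque[tuple[int, int]] = deque()
    for r, c in seed_list:
        if not accepted[r, c]:
            accepted[r, c] = True
            total += img[r, c]
            count += 1
            queue.append((r, c))

    while queue:
        r, c = queue.popleft()
        mean = total / count
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not accepted[nr, nc]:
                if abs(img[nr, nc] - mean) <= tolerance:
                    accepted[nr, nc] = True
                    total += img[nr, nc]
                    count += 1
                    mean = total / count
                    queue.append((nr, nc))
    return accepted.astype(np.uint8)


# ---------------------------------------------------------------------------
# composed algorithms


@dataclass(frozen=True)
class PAParams:
    window: int = DEFAULT_WINDOW
    offset: float = DEFAULT_OFFSET
    ring_outward: int | None = None  # None -> 5 px scaled to image size
    ring_inward: int | None = None
    footprint: str = "disk"


def seg_pa(enface: np.ndarray, mask: np.ndarray, params: PAParams = PAParams()) -> np.ndarray:
    """Peripheral-arcade mask: non-vessel pixels within the marginal ring."""
    if enface.shape != mask.shape:
        raise ValidationError("enface and mask shapes differ")
    outward = params.ring_outward if params.ring_outward is not None else _scaled(DEFAULT_RING_RADIUS, mask.shape)
    inward = params.ring_inward if params.ring_inward is not None else outward
    dmask = ndimage.binary_dilation(np.asarray(mask) > 0, structure=_footprint(outward, params.footprint))
    vessels = binarize_vessels(enface, dmask.astype(np.uint8), params.window, params.offset)
    gaps = invert_within_mask(vessels, dmask.astype(np.uint8))
    ring = ring_mask(mask, outward, inward, params.footprint)
    return (ring.astype(bool) & gaps.astype(bool)).astype(np.uint8)


@dataclass(frozen=True)
class DHParams:
    tolerance: float = DEFAULT_TOLERANCE
    max_outward: int | None = None  # search annulus radius; None -> 50 px scaled
    clahe_kernel: int | None = None
    clahe_clip: float = 0.02
    hypo_margin: float = 0.25  # seeds must be darker than mean - margin * std


def seg_dh(choroid: np.ndarray, mask: np.ndarray, params: DHParams = DHParams()) -> np.ndarray:
    """Dark-halo mask on the choriocapillaris channel.

    Seeds are the lesion contour offset one pixel outward, kept only where
    the enhanced image is hypointense (strictly below mean - hypo_margin *
    std: the halo is a dark structure, so growth must start dark). Growth
    runs on the CLAHE-enhanced image and the result is restricted to a
    bounded search annulus, excluding the lesion interior. A uniformly
    bright choriocapillaris therefore yields an empty halo mask.
    """
    if choroid.shape != mask.shape:
        raise ValidationError("choroid and mask shapes differ")
    m = np.asarray(mask) > 0
    if not m.any():
        raise ValidationError("CNV mask is empty")
    enhanced = enhance_choroid(choroid, params.clahe_kernel, params.clahe_clip)
    outer_contour = ndimage.binary_dilation(m, structure=disk_footprint(1)) & ~m
    hypo_cut = float(enhanced.mean()) - params.hypo_margin * float(enhanced.std())
    seed_mask = outer_contour & (enhanced < hypo_cut)
    if not seed_mask.any():  # nothing hypointense at the margin (or mask fills grid)
        return np.zeros_like(mask, dtype=np.uint8)
    seeds = np.argwhere(seed_mask)
    grown = region_grow(enhanced, seeds, params.tolerance)
    max_outward = params.max_outward if params.max_outward is not None else _scaled(50, mask.shape)
    search = ring_mask(mask, max_outward, 0).astype(bool)
    return (grown.astype(bool) & search & ~m).astype(np.uint8)
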