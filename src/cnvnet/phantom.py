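"""Synthetic OCTA en-face phantom generator.

Generates paired outer-retina / choriocapillaris en-face images with a
central neovascular lesion whose five activity features (well-formed
sea-fan shape, tiny branching vessels, anastomoses/loops, peripheral
arcade, perilesional dark halo) can be toggled independently, together
with pixel-exact ground-truth masks and labels. The generator exists so
the whole pipeline is testable end-to-end without clinical data; it makes
no claim of physical OCTA speckle realism.

Rendering rules (one per activity criterion):

* base lesion: ``n_spokes`` radial vessels from the lesion centre;
* shape (well-formed): chords joining consecutive spoke tips, closing a
  compact sea-fan silhouette; when absent, 2-4 long low-curvature
  filamentous strands leave the lesion disk instead;
* branching: short high-curvature twigs budding off each spoke;
* anastomoses/loops: circumferential links between adjacent spokes at
  mid-radius;
* peripheral arcade: a near-closed marginal arc at the lesion boundary,
  interrupted by a few gaps;
* dark halo: the choriocapillaris channel is darkened multiplicatively
  inside an annulus of width ``halo_width`` around the lesion disk.

Vessel skeletons are rasterized with Bresenham lines (no anti-aliasing)
and thickened by morphological dilation with a disk of radius
``vessel_width // 2``, which keeps the ground truth exactly countable.
Each feature draws from its own child generator of the single seed, so
toggling one feature leaves every other feature's geometry untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import imgio
from .exceptions import ParameterError
from .imgio import ActivityLabels, EnFacePair, SampleRecord

# intensity levels (kept so lesion/background are separable by construction:
# background texture amplitude is <= 0.25 of the vessel intensity)
VESSEL_INTENSITY = 0.9
OUTER_BG = 0.22
OUTER_TEXTURE_AMP = 0.2
CHOROID_BG = 0.6
CHOROID_TEXTURE_AMP = 0.12

# child-rng stream codes, one per independent source of randomness
_STREAMS = {
    "spokes": 1,
    "shape": 2,
    "strands": 3,
    "loops": 4,
    "branching": 5,
    "arcade": 6,
    "texture_outer": 7,
    "texture_choroid": 8,
    "noise_outer": 9,
    "noise_choroid": 10,
}


@dataclass(frozen=True)
class FeatureToggles:
    shape_wellformed: bool = True
    branching: bool = True
    loops: bool = True
    peripheral_arcade: bool = True
    dark_halo: bool = True

    def to_labels(self) -> ActivityLabels:
        return ActivityLabels(
            branch=int(self.branching),
            shape=int(self.shape_wellformed),
            anastomosis_loops=int(self.loops),
            peripheral_arcade=int(self.peripheral_arcade),
            dark_halo=int(self.dark_halo),
        )


@dataclass(frozen=True)
class PhantomConfig:
    """Generative parameters for one phantom en-face pair.

    Defaults emulate the acquisition grid of the study conditions
    (304 x 304 A-scans over 6 x 6 mm^2), a lesion of ~1.2 mm radius, and a
    visible but non-saturating halo.
    """

    image_size: int = 304
    lesion_center: tuple[int, int] | None = None  # (row, col); None = image centre
    lesion_radius: int = 60
    feature_toggles: FeatureToggles = field(default_factory=FeatureToggles)
    vessel_width: int = 3
    n_spokes: int = 9
    halo_width: int = 12
    halo_contrast: float = 0.45
    noise_sigma: float = 0.03
    background_texture_scale: int = 6
    seed: int = 0

    @property
    def center(self) -> tuple[int, int]:
        if self.lesion_center is not None:
            return self.lesion_center
        return (self.image_size // 2, self.image_size // 2)

    def validate(self) -> None:
        if self.lesion_radius <= 0 or self.vessel_width <= 0 or self.halo_width <= 0:
            raise ParameterError("lesion_radius, vessel_width and halo_width must be positive")
        if self.n_spokes < 3:
            raise ParameterError("n_spokes must be >= 3")
        if not 0.0 < self.halo_contrast < 1.0:
            raise ParameterError("halo_contrast must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        cr, cc = self.center
        margin = self.lesion_radius + self.halo_width + self.vessel_width // 2 + 2
        lo = min(cr, cc)
        hi = self.image_size - 1 - max(cr, cc)
        if lo - margin < 0 or hi - margin < 0:
            raise ParameterError(
                f"lesion (radius {self.lesion_radius} + halo {self.halo_width}) exceeds image bounds"
            )


@dataclass
class PhantomSample:
    pair: EnFacePair
    gt_cnv_mask: np.ndarray
    gt_pa_mask: np.ndarray
    gt_dh_mask: np.ndarray
    labels: ActivityLabels
    subject_id: str = "s000"
    image_id: str = "i000"


# ---------------------------------------------------------------------------
# rasterization primitives


def bresenham_line(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """Integer Bresenham rasterization of the segment (r0,c0)-(r1,c1), inclusive."""
    points = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r0 < r1 else -1
    sc = 1 if c0 < c1 else -1
    err = dr - dc
    r, c = r0, c0
    while True:
        points.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dc:
            err -= dc
            r += sr
        if e2 < dr:
            err += dr
            c += sc
    return points


def rasterize_polyline(points: list[tuple[float, float]], shape: tuple[int, int]) -> set[tuple[int, int]]:
    """Rasterize a polyline (float vertices) into a pixel set, clipped to shape."""
    h, w = shape
    pix: set[tuple[int, int]] = set()
    rounded = [(int(round(r)), int(round(c))) for r, c in points]
    for (r0, c0), (r1, c1) in zip(rounded[:-1], rounded[1:]):
        for r, c in bresenham_line(r0, c0, r1, c1):
            if 0 <= r < h and 0 <= c < w:
                pix.add((r, c))
    return pix


def _pixels_to_mask(pixels: set[tuple[int, int]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if pixels:
        rows, cols = zip(*pixels)
        mask[list(rows), list(cols)] = True
    return mask


def _disk_footprint(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    extent = 2 * radius + 1
    rr, cc = np.mgrid[:extent, :extent] - radius
    return (rr**2 + cc**2) <= radius**2


def _rng(config: PhantomConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# lesion geometry


def lesion_polylines(config: PhantomConfig) -> dict[str, list[list[tuple[float, float]]]]:
    """All candidate vessel polylines, keyed by feature.

    Every feature is generated from its own child rng, independent of the
    toggles, so that toggling one feature changes only that feature's pixels.
    ``generate_pair`` selects the subsets the toggles ask for.
    """
    cr, cc = config.center
    radius = float(config.lesion_radius)
    n = config.n_spokes

    rng_sp = _rng(config, "spokes")
    step = 2.0 * np.pi / n
    angles = np.array([i * step + rng_sp.uniform(-0.3, 0.3) * step for i in range(n)])
    tip_radii = radius * rng_sp.uniform(0.88, 1.0, size=n)
    tips = [(cr + rho * np.sin(a), cc + rho * np.cos(a)) for a, rho in zip(angles, tip_radii)]

    spokes = [[(float(cr), float(cc)), tip] for tip in tips]

    # compact sea-fan silhouette: chords joining consecutive tips (closed)
    shape_lines = [[tips[i], tips[(i + 1) % n]] for i in range(n)]

    # filamentous alternative: long low-curvature strands leaving the disk
    rng_st = _rng(config, "strands")
    n_str = int(rng_st.integers(2, 5))
    size = config.image_size
    strands = []
    for _ in range(n_str):
        phi = rng_st.uniform(0, 2 * np.pi)
        length = rng_st.uniform(1.5, 2.4) * radius
        bend = rng_st.uniform(-0.25, 0.25)
        p0 = (cr + 0.5 * radius * np.sin(phi), cc + 0.5 * radius * np.cos(phi))
        p1 = (cr + (0.5 * radius + length / 2) * np.sin(phi + bend / 2),
              cc + (0.5 * radius + length / 2) * np.cos(phi + bend / 2))
        p2 = (cr + (0.5 * radius + length) * np.sin(phi + bend),
              cc + (0.5 * radius + length) * np.cos(phi + bend))
        clip = lambda p: (min(max(p[0], 1.0), size - 2.0), min(max(p[1], 1.0), size - 2.0))
        strands.append([clip(p0), clip(p1), clip(p2)])

    # circumferential links (anastomoses and loops) at mid-radius
    rng_lp = _rng(config, "loops")
    loops = []
    for i in range(n):
        if rng_lp.random() < 0.7:
            a0, a1 = angles[i], angles[(i + 1) % n]
            if a1 <= a0:
                a1 += 2 * np.pi
            rho = 0.55 * radius
            arc_angles = np.linspace(a0, a1, max(3, int((a1 - a0) / 0.08)))
            loops.append([(cr + rho * np.sin(a), cc + rho * np.cos(a)) for a in arc_angles])

    # short high-curvature twigs off each spoke
    rng_br = _rng(config, "branching")
    branches = []
    for a in angles:
        for _ in range(int(rng_br.integers(2, 4))):
            t = rng_br.uniform(0.35, 0.8)
            base = (cr + t * radius * np.sin(a), cc + t * radius * np.cos(a))
            dev = rng_br.uniform(0.6, 1.2) * rng_br.choice([-1.0, 1.0])
            ln = rng_br.uniform(0.12, 0.22) * radius
            mid = (base[0] + 0.5 * ln * np.sin(a + dev), base[1] + 0.5 * ln * np.cos(a + dev))
            kink = dev + rng_br.uniform(0.3, 0.6) * np.sign(dev)
            end = (mid[0] + 0.5 * ln * np.sin(a + kink), mid[1] + 0.5 * ln * np.cos(a + kink))
            branches.append([base, mid, end])

    # near-closed marginal arc with a few gaps
    rng_ar = _rng(config, "arcade")
    n_gaps = 4
    gap_centers = np.sort(rng_ar.uniform(0, 2 * np.pi, size=n_gaps))
    gap_half = np.deg2rad(5.0)
    arc_step = np.deg2rad(2.0)
    arcade = []
    current: list[tuple[float, float]] = []
    for a in np.arange(0, 2 * np.pi, arc_step):
        in_gap = any(min(abs(a - g), 2 * np.pi - abs(a - g)) < gap_half for g in gap_centers)
        if in_gap:
            if len(current) > 1:
                arcade.append(current)
            current = []
        else:
            current.append((cr + radius * np.sin(a), cc + radius * np.cos(a)))
    if len(current) > 1:
        arcade.append(current)

    return {
        "spokes": spokes,
        "shape": shape_lines,
        "strands": strands,
        "loops": loops,
        "branching": branches,
        "arcade": arcade,
    }


def _bandpass_texture(rng: np.random.Generator, size: int, scale: int, amplitude: float) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    band = ndimage.gaussian_filter(noise, scale) - ndimage.gaussian_filter(noise, 2.5 * scale)
    peak = np.abs(band).max()
    if peak > 0:
        band /= peak
    return (amplitude * band).astype(np.float32)


# ---------------------------------------------------------------------------
# generation


def generate_pair(config: PhantomConfig, subject_id: str = "s000", image_id: str = "i000",
                  gain: float = 1.0) -> PhantomSample:
    """Render one phantom en-face pair with ground truth and labels.

    Identical config (and gain) always yields a pixel-identical sample.
    """
    config.validate()
    size = config.image_size
    shape = (size, size)
    toggles = config.feature_toggles
    lines = lesion_polylines(config)

    selected: list[list[tuple[float, float]]] = list(lines["spokes"])
    selected += lines["shape"] if toggles.shape_wellformed else lines["strands"]
    if toggles.loops:
        selected += lines["loops"]
    if toggles.branching:
        selected += lines["branching"]
    if toggles.peripheral_arcade:
        selected += lines["arcade"]

    skeleton_pixels: set[tuple[int, int]] = set()
    for poly in selected:
        skeleton_pixels |= rasterize_polyline(poly, shape)
    skeleton = _pixels_to_mask(skeleton_pixels, shape)

    dil_radius = config.vessel_width // 2
    if dil_radius > 0:
        vessels = ndimage.binary_dilation(skeleton, structure=_disk_footprint(dil_radius))
    else:
        vessels = skeleton

    # geometric ground truth from the analytic lesion disk
    rr, cc_grid = np.mgrid[:size, :size]
    cr, cc = config.center
    dist = np.sqrt((rr - cr) ** 2 + (cc_grid - cc) ** 2)
    gt_cnv = (dist <= config.lesion_radius).astype(np.uint8)
    halo_annulus = (dist > config.lesion_radius) & (dist <= config.lesion_radius + config.halo_width)

    # outer-retina channel
    outer = OUTER_BG + _bandpass_texture(
        _rng(config, "texture_outer"), size, config.background_texture_scale, OUTER_TEXTURE_AMP
    )
    outer = np.clip(outer, 0.0, 1.0)
    outer[vessels] = VESSEL_INTENSITY

    # choriocapillaris channel: granular texture, darkened in the halo annulus
    grain_scale = max(1, config.background_texture_scale // 3)
    choroid = CHOROID_BG + _bandpass_texture(
        _rng(config, "texture_choroid"), size, grain_scale, CHOROID_TEXTURE_AMP
    )
    choroid = np.clip(choroid, 0.0, 1.0)
    if toggles.dark_halo:
        choroid[halo_annulus] *= config.halo_contrast
        gt_dh = halo_annulus.astype(np.uint8)
    else:
        gt_dh = np.zeros(shape, dtype=np.uint8)

    if toggles.peripheral_arcade:
        ring_width = max(3, round(5 * size / 304))
        ring = (dist <= config.lesion_radius + ring_width) & (dist >= config.lesion_radius - ring_width)
        gt_pa = (ring & ~vessels).astype(np.uint8)
    else:
        gt_pa = np.zeros(shape, dtype=np.uint8)

    if config.noise_sigma > 0:
        outer = outer + config.noise_sigma * _rng(config, "noise_outer").standard_normal(shape)
        choroid = choroid + config.noise_sigma * _rng(config, "noise_choroid").standard_normal(shape)
    outer = np.clip(outer * gain, 0.0, 1.0).astype(np.float32)
    choroid = np.clip(choroid * gain, 0.0, 1.0).astype(np.float32)

    pair = EnFacePair(outer, choroid, subject_id=subject_id, image_id=image_id)
    return PhantomSample(pair, gt_cnv, gt_pa, gt_dh, toggles.to_labels(), subject_id, image_id)


def generate_dataset(
    n_subjects: int,
    images_per_subject: int,
    prevalence: tuple[float, float, float, float, float],
    base_config: PhantomConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomSample], list[SampleRecord]]:
    """Generate a grouped phantom cohort; optionally write it to disk.

    Per-image feature labels are i.i.d. Bernoulli draws with the requested
    prevalences (order: shape, branch, loops, arcade, halo — matching
    FeatureToggles field order). Each subject carries a random intensity
    gain and lesion-radius offset, so subject-wise CV differs meaningfully
    from image-wise CV. Returns the samples and their manifest records;
    when ``out_dir`` is given, images/masks/labels/manifest are written
    there and the records point at the files.
    """
    if n_subjects < 1 or images_per_subject < 1:
        raise ParameterError("n_subjects and images_per_subject must be >= 1")
    prevalence = tuple(float(p) for p in prevalence)
    if len(prevalence) != 5 or any(p < 0.0 or p > 1.0 for p in prevalence):
        raise ParameterError("prevalence must be five fractions in [0, 1]")

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    samples: list[PhantomSample] = []
    records: list[SampleRecord] = []
    root = Path(out_dir) if out_dir is not None else None
    if root is not None:
        root.mkdir(parents=True, exist_ok=True)

    for s in range(n_subjects):
        subject_id = f"s{s:03d}"
        gain = float(rng.uniform(0.92, 1.08))
        radius_mult = float(rng.uniform(0.88, 1.12))
        for i in range(images_per_subject):
            image_id = f"{subject_id}_i{i:02d}"
            draws = rng.random(5) < np.asarray(prevalence)
            toggles = FeatureToggles(
                shape_wellformed=bool(draws[0]),
                branching=bool(draws[1]),
                loops=bool(draws[2]),
                peripheral_arcade=bool(draws[3]),
                dark_halo=bool(draws[4]),
            )
            jitter = base_config.image_size // 30
            cr0, cc0 = base_config.center
            center = (
                int(cr0 + rng.integers(-jitter, jitter + 1)),
                int(cc0 + rng.integers(-jitter, jitter + 1)),
            )
            cfg = dataclasses.replace(
                base_config,
                lesion_center=center,
                lesion_radius=max(8, int(round(base_config.lesion_radius * radius_mult))),
                feature_toggles=toggles,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sample = generate_pair(cfg, subject_id=subject_id, image_id=image_id, gain=gain)
            samples.append(sample)

            if root is not None:
                outer_p = f"{image_id}_outer.png"
                choroid_p = f"{image_id}_choroid.png"
                cnv_p = f"{image_id}_cnv_mask.png"
                pa_p = f"{image_id}_pa_mask.png"
                dh_p = f"{image_id}_dh_mask.png"
                imgio.write_image(sample.pair.outer_retina, root / outer_p)
                imgio.write_image(sample.pair.choriocapillaris, root / choroid_p)
                imgio.write_mask(sample.gt_cnv_mask, root / cnv_p)
                imgio.write_mask(sample.gt_pa_mask, root / pa_p)
                imgio.write_mask(sample.gt_dh_mask, root / dh_p)
                records.append(SampleRecord(
                    subject_id=subject_id, image_id=image_id,
                    outer_path=outer_p, choroid_path=choroid_p,
                    cnv_mask_path=cnv_p, pa_mask_path=pa_p, dh_mask_path=dh_p,
                    labels=sample.labels.as_dict(),
                ))
            else:
                records.append(SampleRecord(
                    subject_id=subject_id, image_id=image_id,
                    outer_path="", choroid_path="", cnv_mask_path="",
                    labels=sample.labels.as_dict(),
                ))

    if root is not None:
        imgio.write_labels([(s.subject_id, s.image_id, s.labels) for s in samples], root / "labels.csv")
        cfg_dict = dataclasses.asdict(base_config)
        cfg_dict["feature_toggles"] = dataclasses.asdict(base_config.feature_toggles)
        cfg_dict.update({"n_subjects": n_subjects, "images_per_subject": images_per_subject,
                         "prevalence": list(prevalence), "seed": int(seed)})
        imgio.write_manifest(cfg_dict, records, root / "manifest.json")

    return samples, records
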