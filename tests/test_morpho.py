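"""SEG-PA / SEG-DH primitives against exhaustive brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from cnvnet import evalkit, morpho, phantom
from cnvnet.exceptions import ParameterError, ValidationError
from conftest import small_phantom_config


# ---------------------------------------------------------------------------
# brute-force oracles (loops and set algebra only)


def bruteforce_binarize(img, mask, window, offset):
    half = window // 2
    padded = np.pad(img.astype(np.float64), half, mode="symmetric")
    out = np.zeros(img.shape, dtype=np.uint8)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            win = padded[r : r + window, c : c + window]
            thr = win.mean() - offset * (win.max() - win.min())
            out[r, c] = 1 if (img[r, c] > thr and mask[r, c]) else 0
    return out


def bruteforce_dilate(mask, footprint):
    h, w = mask.shape
    fr, fc = footprint.shape
    cr, cc = fr // 2, fc // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for i in range(fr):
                for j in range(fc):
                    if footprint[i, j]:
                        rr, cc2 = r + i - cr, c + j - cc
                        if 0 <= rr < h and 0 <= cc2 < w:
                            out[rr, cc2] = True
    return out


def bruteforce_erode(mask, footprint):
    h, w = mask.shape
    fr, fc = footprint.shape
    cr, cc = fr // 2, fc // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            ok = True
            for i in range(fr):
                for j in range(fc):
                    if footprint[i, j]:
                        rr, cc2 = r + i - cr, c + j - cc
                        if not (0 <= rr < h and 0 <= cc2 < w) or not mask[rr, cc2]:
                            ok = False
            out[r, c] = ok
    return out


def bruteforce_flood_fixed_mean(img, seeds, tolerance):
    """BFS flood fill accepting |I - seed mean| <= tolerance (fixed criterion)."""
    h, w = img.shape
    mean = np.mean([img[r, c] for r, c in seeds])
    accepted = np.zeros((h, w), dtype=bool)
    queue = sorted(seeds)
    for r, c in queue:
        accepted[r, c] = True
    while queue:
        r, c = queue.pop(0)
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not accepted[nr, nc]:
                if abs(img[nr, nc] - mean) <= tolerance:
                    accepted[nr, nc] = True
                    queue.append((nr, nc))
    return accepted.astype(np.uint8)


# ---------------------------------------------------------------------------
# binarize_vessels


def test_binarize_constant_image_is_all_zero():
    img = np.full((20, 20), 0.4)
    out = morpho.binarize_vessels(img, np.ones((20, 20)), window=5, offset=0.0)
    assert not out.any()


def test_binarize_bright_line_recovers_exactly_the_line():
    img = np.zeros((24, 24))
    img[12, :] = 1.0
    mask = np.ones((24, 24), dtype=np.uint8)
    out = morpho.binarize_vessels(img, mask, window=15, offset=0.0)
    expected = np.zeros((24, 24), dtype=np.uint8)
    expected[12, :] = 1
    assert np.array_equal(out, expected)


def test_binarize_matches_bruteforce_on_random_grids(rng):
    for window in (3, 5, 15):
        for offset in (0.0, -0.15, 0.1):
            img = rng.random((20, 20))
            mask = (rng.random((20, 20)) > 0.3).astype(np.uint8)
            got = morpho.binarize_vessels(img, mask, window=window, offset=offset)
            assert np.array_equal(got, bruteforce_binarize(img, mask, window, offset))


def test_binarize_inversion_swaps_contrast_polarity(rng):
    """Inverting intensities turns strict local-contrast foreground into
    background wherever the pixel is not exactly at the local threshold."""
    img = rng.random((16, 16))
    mask = np.ones((16, 16), dtype=np.uint8)
    a = morpho.binarize_vessels(img, mask, window=5, offset=0.0)
    b = morpho.binarize_vessels(1.0 - img, mask, window=5, offset=0.0)
    # a pixel above its local mean in img is below it in 1 - img
    assert not (a & b).any()
    assert np.array_equal(b, bruteforce_binarize(1.0 - img, mask, 5, 0.0))


def test_binarize_even_window_rejected():
    with pytest.raises(ParameterError):
        morpho.binarize_vessels(np.zeros((8, 8)), np.ones((8, 8)), window=4)


# ---------------------------------------------------------------------------
# invert_within_mask


def test_invert_within_mask_truth_table(rng):
    binary = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    out = morpho.invert_within_mask(binary, mask)
    for r in range(8):
        for c in range(8):
            assert out[r, c] == (mask[r, c] and not binary[r, c])
    assert not morpho.invert_within_mask(mask, mask).any()
    assert np.array_equal(morpho.invert_within_mask(np.zeros((8, 8)), mask), mask)
    with pytest.raises(ValidationError):
        morpho.invert_within_mask(binary, np.ones((4, 4)))


# ---------------------------------------------------------------------------
# ring_mask


def test_ring_of_single_pixel_square_element_is_eight_neighbourhood():
    mask = np.zeros((5, 5), dtype=np.uint8)
    mask[2, 2] = 1
    ring = morpho.ring_mask(mask, outward=1, inward=0, footprint="square")
    expected = np.zeros((5, 5), dtype=np.uint8)
    expected[1:4, 1:4] = 1
    expected[2, 2] = 0
    assert np.array_equal(ring, expected)


def test_ring_degenerate_masks():
    assert not morpho.ring_mask(np.zeros((6, 6)), outward=2).any()
    assert not morpho.ring_mask(np.ones((6, 6)), outward=2, inward=0).any()
    with pytest.raises(ParameterError):
        morpho.ring_mask(np.ones((6, 6)), outward=0)


def test_ring_matches_bruteforce_set_algebra(rng):
    for footprint in ("disk", "square"):
        for outward, inward in ((1, 0), (2, 1), (3, 3)):
            mask = (rng.random((16, 16)) > 0.8).astype(np.uint8)
            got = morpho.ring_mask(mask, outward, inward, footprint)
            fp_out = (morpho.disk_footprint if footprint == "disk" else morpho.square_footprint)(outward)
            fp_in = (morpho.disk_footprint if footprint == "disk" else morpho.square_footprint)(inward)
            dil = bruteforce_dilate(mask.astype(bool), fp_out)
            ero = bruteforce_erode(mask.astype(bool), fp_in) if inward > 0 else mask.astype(bool)
            assert np.array_equal(got.astype(bool), dil & ~ero)


def test_ring_area_monotone_in_both_radii(rng):
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10:20, 12:24] = 1
    areas_out = [morpho.ring_mask(mask, o, 2).sum() for o in (1, 2, 4, 6)]
    assert areas_out == sorted(areas_out)
    areas_in = [morpho.ring_mask(mask, 3, i).sum() for i in (0, 1, 3, 5)]
    assert areas_in == sorted(areas_in)


# ---------------------------------------------------------------------------
# region_grow


def test_region_grow_uniform_image_fills_grid():
    out = morpho.region_grow(np.full((12, 12), 0.5), [(3, 3)], tolerance=0.1)
    assert out.all()


def test_region_grow_dark_annulus_fixture():
    """Bright disk (1.0) inside a dark annulus (0.2) on a 0.8 background:
    a seed in the annulus with tolerance 0.3 grows to exactly the annulus."""
    size = 64
    rr, cc = np.mgrid[:size, :size]
    dist = np.sqrt((rr - 32) ** 2 + (cc - 32) ** 2)
    img = np.full((size, size), 0.8)
    img[dist <= 20] = 0.2
    img[dist <= 12] = 1.0
    annulus = ((dist > 12) & (dist <= 20))
    seed = (32 - 16, 32)
    assert annulus[seed]
    got = morpho.region_grow(img, [seed], tolerance=0.3)
    assert np.array_equal(got.astype(bool), annulus)
    # fixed-mean BFS oracle agrees on this piecewise-constant fixture
    assert np.array_equal(got, bruteforce_flood_fixed_mean(img, [seed], 0.3))


def test_region_grow_zero_tolerance_is_connected_component(rng):
    img = (rng.integers(0, 4, size=(24, 24)) / 4.0)
    seed_val = img[5, 5]
    labeled, _ = ndimage.label(img == seed_val, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    expected = labeled == labeled[5, 5]
    got = morpho.region_grow(img, [(5, 5)], tolerance=0.0)
    assert np.array_equal(got.astype(bool), expected)


def test_region_grow_contains_seeds_and_is_connected(rng):
    img = rng.random((20, 20))
    seeds = [(2, 2), (2, 3)]
    out = morpho.region_grow(img, seeds, tolerance=0.2)
    assert all(out[r, c] for r, c in seeds)
    labeled, n = ndimage.label(out, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    assert n == 1


def test_region_grow_validation():
    with pytest.raises(ValidationError):
        morpho.region_grow(np.zeros((4, 4)), [], tolerance=0.1)
    with pytest.raises(ValidationError):
        morpho.region_grow(np.zeros((4, 4)), [(9, 0)], tolerance=0.1)
    with pytest.raises(ParameterError):
        morpho.region_grow(np.zeros((4, 4)), [(0, 0)], tolerance=-1)


# ---------------------------------------------------------------------------
# enhance_choroid


def test_enhance_constant_image_unchanged():
    img = np.full((32, 32), 0.3)
    assert np.array_equal(morpho.enhance_choroid(img), img.astype(np.float32))


def test_enhance_respects_unit_range_and_raises_entropy(rng):
    out = morpho.enhance_choroid(rng.random((64, 64)).astype(np.float32))
    assert out.min() >= 0.0 and out.max() <= 1.0
    # low-contrast fixture: intensities squeezed into [0.45, 0.55]
    low = 0.45 + 0.1 * rng.random((64, 64))

    def entropy(img):
        hist, _ = np.histogram((img * 255).astype(np.uint8), bins=256, range=(0, 255))
        p = hist / hist.sum()
        p = p[p > 0]
        return -(p * np.log2(p)).sum()

    assert entropy(morpho.enhance_choroid(low)) >= entropy(low)


# ---------------------------------------------------------------------------
# composed algorithms


def test_seg_pa_equals_primitive_composition(rng):
    enface = rng.random((32, 32)).astype(np.float32)
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10:22, 10:22] = 1
    params = morpho.PAParams(window=5, offset=0.0, ring_outward=2, ring_inward=2)
    got = morpho.seg_pa(enface, mask, params)
    dmask = bruteforce_dilate(mask.astype(bool), morpho.disk_footprint(2)).astype(np.uint8)
    vessels = morpho.binarize_vessels(enface, dmask, window=5, offset=0.0)
    gaps = morpho.invert_within_mask(vessels, dmask)
    ring = morpho.ring_mask(mask, 2, 2)
    assert np.array_equal(got, (ring.astype(bool) & gaps.astype(bool)).astype(np.uint8))
    # arcade-mask never overlaps binarized vessels
    assert not (got.astype(bool) & vessels.astype(bool)).any()


def test_seg_pa_all_vessels_gives_empty_mask():
    """A strict row-major gradient with offset 1.0 binarizes to all-vessel
    inside the ring, so no inter-vessel space survives."""
    size = 24
    enface = (np.arange(size * size, dtype=np.float64).reshape(size, size)) / (size * size)
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[10:14, 10:14] = 1
    params = morpho.PAParams(window=3, offset=1.0, ring_outward=2, ring_inward=2)
    dmask = morpho.ring_mask(mask, 2, 2) | mask
    vessels = morpho.binarize_vessels(enface, np.ones_like(mask), window=3, offset=1.0)
    ring = morpho.ring_mask(mask, 2, 2)
    assert vessels[ring.astype(bool)].all()  # precondition: all-vessel in the ring
    assert not morpho.seg_pa(enface, mask, params).any()


def test_seg_pa_arcade_removal_increases_open_margin():
    cfg_on = small_phantom_config(seed=21)
    cfg_off = small_phantom_config(seed=21, peripheral_arcade=False)
    on = phantom.generate_pair(cfg_on)
    off = phantom.generate_pair(cfg_off)
    area_on = morpho.seg_pa(on.pair.outer_retina, on.gt_cnv_mask).sum()
    area_off = morpho.seg_pa(off.pair.outer_retina, off.gt_cnv_mask).sum()
    assert area_on > 0
    assert area_off > area_on


def test_seg_dh_recovers_phantom_halo():
    s = phantom.generate_pair(small_phantom_config(seed=22))
    dh = morpho.seg_dh(s.pair.choriocapillaris, s.gt_cnv_mask)
    assert evalkit.dice_coefficient(dh, s.gt_dh_mask) >= 0.7
    # never leaks into the lesion interior
    assert not (dh.astype(bool) & (s.gt_cnv_mask > 0)).any()


def test_seg_dh_uniform_bright_choroid_grows_nowhere():
    mask = np.zeros((64, 64), dtype=np.uint8)
    mask[28:36, 28:36] = 1
    choroid = np.full((64, 64), 0.9, dtype=np.float32)
    out = morpho.seg_dh(choroid, mask, morpho.DHParams(tolerance=0.01))
    assert not out.any()  # no hypointense margin to seed from


def test_seg_dh_empty_mask_rejected():
    with pytest.raises(ValidationError):
        morpho.seg_dh(np.zeros((16, 16)), np.zeros((16, 16)))
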