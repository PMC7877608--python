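"""Motion-channel tests against brute-force imaging oracles."""

import numpy as np
import pytest
from scipy import ndimage

from hybridtrack.config import MotionConfig
from hybridtrack.foreground import (
    RunningStatsBackground,
    count_change_regions,
    denoise_mask,
    extract_blobs,
)

# ---------------------------------------------------------------- oracles


def median_then_erode_oracle(mask: np.ndarray, med: int, ero: int) -> np.ndarray:
    """Direct per-pixel window scan: majority vote over a med×med reflect-padded
    window, then erosion requiring a full ero×ero window (zero-padded)."""
    out = mask.astype(bool)
    if med > 1:
        r = med // 2
        padded = np.pad(out, r, mode="symmetric")  # edge-duplicating reflection
        res = np.zeros_like(out)
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                win = padded[i : i + med, j : j + med]
                res[i, j] = win.sum() * 2 > med * med
        out = res
    if ero > 1:
        pl = (ero - 1) // 2
        pr = ero - 1 - pl
        padded = np.pad(out, ((pl, pr), (pl, pr)), constant_values=False)
        res = np.zeros_like(out)
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                res[i, j] = padded[i : i + ero, j : j + ero].all()
        out = res
    return out


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """Recursive-style (stack-based) 8-connected flood fill."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not seen[si, sj]:
                comp = set()
                stack = [(si, sj)]
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    comp.add((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (
                                0 <= ni < h
                                and 0 <= nj < w
                                and mask[ni, nj]
                                and not seen[ni, nj]
                            ):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                comps.append(comp)
    return comps


# ------------------------------------------------------- background model


def test_static_scene_gives_all_background_after_warmup():
    model = RunningStatsBackground(warmup_frames=10)
    frame = np.full((20, 20), 100.0)
    for _ in range(50):
        mask = model.apply(frame)
    assert not mask.mask.any()


def test_warmup_masks_are_suppressed():
    model = RunningStatsBackground(warmup_frames=5)
    rng = np.random.default_rng(0)
    for k in range(5):
        mask = model.apply(rng.uniform(0, 255, (16, 16)))
        assert not mask.mask.any(), f"frame {k} should be suppressed"
        assert mask.frame_index == k


def test_translating_bright_square_recovered():
    """Post-warm-up mask covers >= 80% of the square's true pixels, judged
    against a thresholded absolute difference from the known background."""
    h, w = 60, 120
    bg = np.full((h, w), 50.0)
    model = RunningStatsBackground(warmup_frames=30)
    for k in range(60):
        frame = bg.copy()
        x0 = 5 + 2 * k
        frame[20:30, x0 : x0 + 10] = 200.0
        mask = model.apply(frame)
    oracle = np.abs(frame - bg) > 25
    overlap = (mask.mask & oracle).sum()
    assert overlap >= 0.8 * oracle.sum()


def test_dimension_mismatch_rejected():
    model = RunningStatsBackground()
    model.apply(np.zeros((10, 10)))
    with pytest.raises(ValueError):
        model.apply(np.zeros((12, 12)))


# --------------------------------------------------------------- denoise


def test_isolated_pixel_removed_by_median():
    mask = np.zeros((9, 9), dtype=bool)
    mask[4, 4] = True
    cfg = MotionConfig(median_kernel=3, erosion_kernel=1)
    assert not denoise_mask(mask, cfg).mask.any()


def test_empty_mask_stays_empty():
    cfg = MotionConfig(median_kernel=5, erosion_kernel=3)
    assert not denoise_mask(np.zeros((16, 16), dtype=bool), cfg).mask.any()


@pytest.mark.parametrize("seed", range(30))
def test_denoise_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((64, 64)) < 0.4
    cfg = MotionConfig(median_kernel=5, erosion_kernel=3)
    got = denoise_mask(mask, cfg).mask
    want = median_then_erode_oracle(mask, 5, 3)
    np.testing.assert_array_equal(got, want)


@pytest.mark.parametrize("seed", range(10))
def test_erosion_output_subset_of_median_output(seed):
    rng = np.random.default_rng(100 + seed)
    mask = rng.random((48, 48)) < 0.5
    med_only = denoise_mask(mask, MotionConfig(median_kernel=5, erosion_kernel=1)).mask
    full = denoise_mask(mask, MotionConfig(median_kernel=5, erosion_kernel=3)).mask
    assert not (full & ~med_only).any()


# ------------------------------------------------------------------ blobs


def test_extract_blobs_empty_mask():
    assert extract_blobs(np.zeros((10, 10), dtype=bool), min_area=1) == []


def test_extract_blobs_square_centroid_and_area_filter():
    mask = np.zeros((64, 64), dtype=bool)
    mask[5:25, 5:25] = True  # 20x20 at top-left pixel (5,5)
    mask[40:43, 40:43] = True  # 3x3 rejected by min_area
    blobs = extract_blobs(mask, min_area=50)
    assert len(blobs) == 1
    assert blobs[0].area == 400
    assert blobs[0].centroid == (14.5, 14.5)


def test_blob_exactly_at_min_area_is_kept():
    mask = np.zeros((16, 16), dtype=bool)
    mask[2:5, 2:5] = True  # area 9
    assert len(extract_blobs(mask, min_area=9)) == 1
    assert len(extract_blobs(mask, min_area=10)) == 0


@pytest.mark.parametrize("seed", range(30))
def test_extract_blobs_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    mask = rng.random((40, 40)) < 0.25
    min_area = 3
    comps = [c for c in flood_fill_components(mask) if len(c) >= min_area]
    want = sorted(
        (
            len(c),
            round(sum(j for _, j in c) / len(c), 9),
            round(sum(i for i, _ in c) / len(c), 9),
        )
        for c in comps
    )
    got = sorted(
        (b.area, round(b.centroid[0], 9), round(b.centroid[1], 9))
        for b in extract_blobs(mask, min_area)
    )
    assert got == want


def test_blob_areas_partition_qualifying_foreground():
    rng = np.random.default_rng(7)
    mask = rng.random((50, 50)) < 0.3
    min_area = 4
    blobs = extract_blobs(mask, min_area)
    comps = flood_fill_components(mask)
    expected = sum(len(c) for c in comps if len(c) >= min_area)
    assert sum(b.area for b in blobs) == expected


# ------------------------------------------------- change-region counting


def test_count_change_regions_empty():
    cfg = MotionConfig()
    assert count_change_regions(np.zeros((32, 32), dtype=bool), (16, 16), 10, cfg) == 0


def test_count_change_regions_distance_membership():
    """Three well-separated squares at centroid distances ~{5, 10, 200} from
    the query center; radius 50 admits exactly two."""
    mask = np.zeros((300, 420), dtype=bool)
    center = (150.0, 150.0)
    for dx, dy in ((5, 0), (0, 10), (200, 0)):
        # 9x9 square with integer centroid (150 + dx, 150 + dy)
        r0, c0 = 150 + dy - 4, 150 + dx - 4
        mask[r0 : r0 + 9, c0 : c0 + 9] = True
    cfg = MotionConfig()
    assert count_change_regions(mask, center, radius=50, cfg=cfg) == 2


@pytest.mark.parametrize("seed", range(10))
def test_count_change_regions_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(300 + seed)
    mask = rng.random((40, 40)) < 0.2
    cfg = MotionConfig(region_change_floor=2)
    center = (20.0, 20.0)
    radius = 12.0
    comps = [c for c in flood_fill_components(mask) if len(c) >= 2]
    want = 0
    for c in comps:
        cy = sum(i for i, _ in c) / len(c)
        cx = sum(j for _, j in c) / len(c)
        if (cx - center[0]) ** 2 + (cy - center[1]) ** 2 <= radius**2:
            want += 1
    assert count_change_regions(mask, center, radius, cfg) == want


def test_count_change_regions_monotonicity():
    rng = np.random.default_rng(9)
    mask = rng.random((48, 48)) < 0.2
    center = (24.0, 24.0)
    counts = [
        count_change_regions(mask, center, r, MotionConfig(region_change_floor=2))
        for r in (5, 10, 20, 40)
    ]
    assert counts == sorted(counts)
    lo_floor = count_change_regions(mask, center, 20, MotionConfig(region_change_floor=1))
    hi_floor = count_change_regions(mask, center, 20, MotionConfig(region_change_floor=5))
    assert hi_floor <= lo_floor
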