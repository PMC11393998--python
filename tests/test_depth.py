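"""Depth image IO and the conditional keypoint depth filter."""

import numpy as np
import pytest
from PIL import Image

import bovimetry as bv
from bovimetry.depth import DepthFilterParams, DepthImage, _round_half_away
from bovimetry.errors import (
    DepthLoadError,
    MissingLandmarkError,
    NoReferenceDepthError,
    OutOfBoundsError,
)
from bovimetry.keypoints import Keypoint, KeypointSet


# ----------------------------------------------------------------- loading
def test_load_constant_16bit_png(tmp_path):
    img = DepthImage(np.full((4, 4), 3000, dtype=np.int64))
    bv.save_depth_image(img, tmp_path / "d.png")
    loaded = bv.load_depth_image(tmp_path / "d.png")
    assert loaded.values.shape == (4, 4)
    assert np.all(loaded.values == 3000)


def test_load_multichannel_takes_channel_zero(tmp_path):
    ramp = np.arange(12, dtype=np.uint8).reshape(3, 4)
    rgb = np.stack([ramp, ramp * 0 + 7, ramp * 0 + 9], axis=-1)
    Image.fromarray(rgb, mode="RGB").save(tmp_path / "rgb.png")
    loaded = bv.load_depth_image(tmp_path / "rgb.png")
    assert np.array_equal(loaded.values, ramp)


def test_load_missing_file_raises(tmp_path):
    with pytest.raises(DepthLoadError):
        bv.load_depth_image(tmp_path / "nope.png")


def test_save_load_roundtrip_is_exact(tmp_path, rng):
    vals = rng.integers(0, 7001, size=(32, 48))
    bv.save_depth_image(DepthImage(vals), tmp_path / "r.png")
    assert np.array_equal(bv.load_depth_image(tmp_path / "r.png").values, vals)


# ---------------------------------------------------------- reference depth
def _img(arr):
    return DepthImage(np.asarray(arr, dtype=np.int64))


def test_reference_constant_window():
    img = _img(np.full((9, 9), 3000))
    assert bv.reference_depth(img, (4, 4), (4, 4)) == 3000.0


def test_reference_excludes_zero_from_mean():
    grid = np.full((9, 9), 3000)
    grid[4, 4] = 0
    # brute-force mean over the valid 8 of 9 window samples
    assert bv.reference_depth(_img(grid), (4, 4), (4, 4)) == pytest.approx(3000.0)
    grid[4, 4] = 3090
    assert bv.reference_depth(_img(grid), (4, 4), (4, 4)) == pytest.approx(3010.0)


def test_reference_excludes_out_of_range_depth():
    grid = np.full((9, 9), 3000)
    grid[4, 5] = 8000
    assert bv.reference_depth(_img(grid), (4, 4), (4, 4)) == pytest.approx(3000.0)


def test_reference_exactly_7000_is_valid():
    grid = np.full((9, 9), 7000)
    assert bv.reference_depth(_img(grid), (4, 4), (4, 4)) == 7000.0


def test_reference_empty_window_errors_then_grows():
    grid = np.full((15, 15), 0)
    grid[3, 7] = 3000  # outside the 3x3, inside the grown 7x7
    with pytest.raises(NoReferenceDepthError):
        bv.reference_depth(_img(grid), (7, 7), (7, 7))
    p = DepthFilterParams(grow_reference=True)
    assert bv.reference_depth(_img(grid), (7, 7), (7, 7), p) == 3000.0


def test_reference_window_must_fit_in_image():
    img = _img(np.full((9, 9), 3000))
    with pytest.raises(OutOfBoundsError):
        bv.reference_depth(img, (0, 0), (0, 0))


def test_midpoint_rounds_half_away_from_zero():
    assert _round_half_away(2.5) == 3
    assert _round_half_away(2.4) == 2
    assert _round_half_away(-2.5) == -3


# --------------------------------------------------- nearest valid search
def test_center_pixel_hit_at_radius_zero():
    grid = np.full((9, 9), 2950)
    assert bv.find_nearest_valid_depth(_img(grid), (4, 4), 3000.0) == 2950.0


def test_recovery_from_ring_radius_two():
    grid = np.zeros((9, 9), dtype=int)
    grid[2, 3] = 3100  # Chebyshev radius 2 from (4, 4)
    d = bv.find_nearest_valid_depth(_img(grid), (4, 4), 3000.0)
    # exhaustive scan oracle: the only qualifying pixel in the image
    assert d == 3100.0


def test_minimal_ring_wins_over_farther_candidate():
    grid = np.zeros((11, 11), dtype=int)
    grid[5, 7] = 3100   # radius 2
    grid[5, 9] = 2900   # radius 4
    assert bv.find_nearest_valid_depth(_img(grid), (5, 5), 3000.0) == 3100.0


def test_tie_on_same_ring_broken_by_scan_order():
    grid = np.zeros((9, 9), dtype=int)
    grid[3, 4] = 3100  # (dy, dx) = (-1, 0)
    grid[5, 4] = 2900  # (dy, dx) = (+1, 0)
    # increasing dy scans the dy = -1 row first
    assert bv.find_nearest_valid_depth(_img(grid), (4, 4), 3000.0) == 3100.0


def test_no_qualifying_candidate_returns_absent():
    grid = np.full((9, 9), 8000)
    grid[4, 4] = 0
    grid[4, 5] = 3600  # valid range but |d - ref| > 500
    assert bv.find_nearest_valid_depth(_img(grid), (4, 4), 3000.0) is None


def test_raster_mode_reproduces_square_scan_order():
    grid = np.zeros((9, 9), dtype=int)
    grid[4, 2] = 3100  # dx = -2 -> first hit of the dx-major raster
    grid[3, 4] = 2900  # ring distance 1 -> nearest for the ring search
    img = _img(grid)
    assert bv.find_nearest_valid_depth(img, (4, 4), 3000.0) == 2900.0
    p = DepthFilterParams(search="raster")
    assert bv.find_nearest_valid_depth(img, (4, 4), 3000.0, p) == 3100.0


def test_search_is_deterministic(rng):
    grid = rng.integers(0, 7001, size=(21, 21))
    img = _img(grid)
    first = [bv.find_nearest_valid_depth(img, (10, 10), 3000.0) for _ in range(3)]
    assert first[0] == first[1] == first[2]


def test_center_outside_image_raises():
    with pytest.raises(OutOfBoundsError):
        bv.find_nearest_valid_depth(_img(np.zeros((5, 5))), (10, 2), 3000.0)


# ------------------------------------------------------------- localization
def test_noiseless_scene_filter_is_identity(default_scene, K):
    _, img, kps = default_scene
    wk = bv.localize_keypoints(img, kps, K)
    assert not wk.missing
    for name in bv.LANDMARKS:
        iu, iv = _round_half_away(kps[name].u), _round_half_away(kps[name].v)
        assert wk.depths[name] == img.at(iu, iv)


def test_refined_depths_satisfy_filter_invariants(default_scene, K):
    _, img, kps = default_scene
    noisy = bv.dropout_near_keypoints(img, kps, 0.2, seed=5)
    p = DepthFilterParams()
    wk = bv.localize_keypoints(noisy, kps, K, p)
    for name, d in wk.depths.items():
        assert p.valid_min < d <= p.valid_max
        assert abs(d - wk.reference) <= p.ref_tolerance


def test_dropout_at_withers_recovered_from_ring(default_scene, K):
    _, img, kps = default_scene
    base = bv.body_height(bv.localize_keypoints(img, kps, K))
    vals = img.values.copy()
    iu, iv = round(kps["Withers"].u), round(kps["Withers"].v)
    vals[iv - 1: iv + 2, iu - 1: iu + 2] = 0
    wk = bv.localize_keypoints(DepthImage(vals), kps, K)
    assert "Withers" in wk.points
    assert abs(bv.body_height(wk) - base) / base < 0.01


def test_scene_of_invalid_depths_raises_no_reference(K):
    img = _img(np.full((720, 1280), 8000))
    kps = KeypointSet(points={
        "Shoulder": Keypoint(400, 390), "Pin": Keypoint(830, 390)})
    with pytest.raises(NoReferenceDepthError):
        bv.localize_keypoints(img, kps, K)


def test_missing_shoulder_blocks_reference(default_scene, K):
    _, img, kps = default_scene
    pruned = KeypointSet(points={n: kps[n] for n in bv.LANDMARKS if n != "Shoulder"})
    with pytest.raises(MissingLandmarkError, match="Shoulder"):
        bv.localize_keypoints(img, pruned, K)


def test_unfindable_landmark_marked_missing_not_fabricated(default_scene, K):
    _, img, kps = default_scene
    vals = img.values.copy()
    iu, iv = round(kps["Withers"].u), round(kps["Withers"].v)
    r = 25  # larger than the default max_radius
    vals[max(0, iv - r): iv + r + 1, max(0, iu - r): iu + r + 1] = 0
    wk = bv.localize_keypoints(DepthImage(vals), kps, K)
    assert "Withers" in wk.missing
    assert "Withers" not in wk.points
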