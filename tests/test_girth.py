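"""The girth curve pipeline: profile, RBF smoothing, mirror, spline, length."""

import numpy as np
import pytest

import bovimetry as bv
from bovimetry.depth import DepthImage
from bovimetry.errors import (
    DegenerateChordError,
    InsufficientProfileError,
    ValidationError,
)
from bovimetry.girth import (
    Curve3D,
    GirthConfig,
    close_curve_spline,
    generate_intermediate_points,
    mirror_half_curve,
    polyline_length,
    rbf_smooth_curve,
    sample_surface_profile,
)


# ------------------------------------------------------ intermediate points
def test_intermediate_points_midpoint_and_ends():
    c = generate_intermediate_points([0, 0, 0], [0, 10, 0], 3)
    assert np.allclose(c.points, [[0, 0, 0], [0, 5, 0], [0, 10, 0]])


def test_intermediate_points_collinear(rng):
    a, b = rng.normal(0, 100, 3), rng.normal(0, 100, 3)
    c = generate_intermediate_points(a, b, 17)
    assert np.allclose(c.points[0], a) and np.allclose(c.points[-1], b)
    cross = np.cross(c.points - a, b - a)
    assert np.max(np.linalg.norm(cross, axis=1)) < 1e-9 * np.linalg.norm(b - a) ** 2


def test_intermediate_points_degenerate_chord():
    with pytest.raises(DegenerateChordError):
        generate_intermediate_points([1, 2, 3], [1, 2, 3], 5)


# ----------------------------------------------------------- RBF smoothing
def test_rbf_zero_smoothing_interpolates_exactly(rng):
    pts = rng.normal(0, 100, (12, 3))
    # refine 1 evaluates on the node grid itself: exact reproduction
    nodes = rbf_smooth_curve(Curve3D(pts), smooth_factor=0.0, refine_factor=1)
    assert np.allclose(nodes.points, pts, rtol=1e-6, atol=1e-6)
    dense = rbf_smooth_curve(Curve3D(pts), smooth_factor=0.0, refine_factor=10)
    assert len(dense) == 120
    # the densified curve passes close to every input sample
    for p in pts:
        assert np.min(np.linalg.norm(dense.points - p, axis=1)) < 15.0


def test_rbf_reproduces_collinear_input():
    t = np.linspace(0, 1, 20)
    pts = np.array([10, -5, 2.0]) + t[:, None] * np.array([100, 300, -50.0])
    for sf in (0.0, 1.0, 10.0):
        dense = rbf_smooth_curve(Curve3D(pts), smooth_factor=sf)
        a, b = pts[0], pts[-1] - pts[0]
        cross = np.cross(dense.points - a, b)
        assert np.max(np.linalg.norm(cross, axis=1)) / np.linalg.norm(b) ** 2 < 1e-6


def test_rbf_smoothing_damps_an_outlier(rng):
    t = np.linspace(0, np.pi, 25)
    clean = np.stack([np.zeros_like(t), 300 * np.sin(t), 300 * np.cos(t)], axis=1)
    noisy = clean.copy()
    noisy[12, 1] += 50.0
    smoothed = rbf_smooth_curve(Curve3D(noisy), smooth_factor=50.0)
    ref = rbf_smooth_curve(Curve3D(clean), smooth_factor=50.0)
    raw_dev = np.abs(noisy[:, 1] - clean[:, 1]).max()
    smooth_dev = np.abs(smoothed.points[:, 1] - ref.points[:, 1]).max()
    assert smooth_dev < raw_dev


def test_rbf_rejects_degenerate_curves():
    with pytest.raises(ValidationError):
        rbf_smooth_curve(Curve3D(np.zeros((3, 2))), 0.0)  # wrong dim
    with pytest.raises(ValidationError):
        Curve3D(np.zeros((2, 3)))  # too few points


# ------------------------------------------------------------------ mirror
def test_mirror_fixes_points_on_the_chord():
    c1, c2 = np.array([0.0, -300, 2900]), np.array([0.0, 300, 2900])
    pts = np.stack([c1, (c1 + c2) / 2, c2])
    mirrored = mirror_half_curve(Curve3D(pts), c1, c2)
    assert np.allclose(mirrored.points, pts[::-1], atol=1e-9)


def test_mirror_midpoints_lie_on_chord_plane(rng):
    c1, c2 = np.array([100.0, -250, 3000]), np.array([-50.0, 400, 2800])
    pts = rng.normal(0, 200, (20, 3)) + (c1 + c2) / 2
    mirrored = mirror_half_curve(Curve3D(pts), c1, c2)
    mid = (pts + mirrored.points[::-1]) / 2.0
    e1 = (c2 - c1) / np.linalg.norm(c2 - c1)
    origin = (c1 + c2) / 2
    w = -origin - (-origin @ e1) * e1  # camera at 0 -> chord-plane normal
    e2 = w / np.linalg.norm(w)
    assert np.max(np.abs((mid - origin) @ e2)) < 1e-9 * 3000


def test_mirror_of_semicircle_completes_the_circle():
    center = np.array([0.0, 0.0, 3000.0])
    r = 400.0
    theta = np.linspace(-np.pi / 2, np.pi / 2, 50)
    # bulge toward the camera (smaller Z), chord along Y
    half = center + np.stack(
        [np.zeros_like(theta), r * np.sin(theta), -r * np.cos(theta)], axis=1)
    c1, c2 = half[0], half[-1]
    mirrored = mirror_half_curve(Curve3D(half), c1, c2)
    full = np.vstack([half, mirrored.points])
    radii = np.linalg.norm(full - center, axis=1)
    assert np.max(np.abs(radii - r)) < 1e-6


def test_mirror_literal_y_negates_camera_y():
    pts = np.array([[1.0, 2.0, 3.0], [4.0, -5.0, 6.0], [7.0, 8.0, 9.0]])
    m = mirror_half_curve(Curve3D(pts), pts[0], pts[-1], frame="literal_y")
    assert np.allclose(m.points[:, 1], -pts[:, 1])
    assert np.allclose(m.points[:, [0, 2]], pts[:, [0, 2]])


def test_mirror_degenerate_chord_errors():
    pts = np.zeros((5, 3)) + [0, 0, 3000]
    with pytest.raises(DegenerateChordError):
        mirror_half_curve(Curve3D(pts), pts[0], pts[0])


# ------------------------------------------------------------------ spline
def _circle_points(n, r=400.0, center=(0.0, 0.0, 3000.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c = np.asarray(center)
    return c + np.stack([np.cos(th) * r, np.sin(th) * r, np.zeros(n)], axis=1)


def test_closed_spline_on_dense_circle_is_accurate():
    pts = _circle_points(32)
    dense = close_curve_spline(Curve3D(pts), "periodic", 10)
    radii = np.linalg.norm(dense.points - [0, 0, 3000], axis=1)
    assert np.max(np.abs(radii - 400.0)) < 0.5


def test_closed_spline_on_sparse_circle_within_spline_theory_bound():
    # 16 knots leave ~22.5 deg spans; chord-parameterized cubic
    # interpolation deviates ~0.0034 r between knots
    pts = _circle_points(16)
    dense = close_curve_spline(Curve3D(pts), "periodic", 10)
    radii = np.linalg.norm(dense.points - [0, 0, 3000], axis=1)
    assert np.max(np.abs(radii - 400.0)) < 2.0


def test_spline_interpolates_its_knots():
    pts = _circle_points(24)
    dense = close_curve_spline(Curve3D(pts), "periodic", 40)
    # dense samples are ~2.6 mm apart along the loop; an interpolating
    # spline must pass within half a sample step of every knot
    for p in pts:
        assert np.min(np.linalg.norm(dense.points - p, axis=1)) < 1.5


def test_spline_output_count_is_refine_times_input():
    pts = _circle_points(20)
    assert len(close_curve_spline(Curve3D(pts), "periodic", 10)) == 200
    assert len(close_curve_spline(Curve3D(pts), "open", 7)) == 140


def test_spline_dedups_consecutive_duplicates():
    pts = _circle_points(24)
    doubled = np.repeat(pts, 2, axis=0)
    dense = close_curve_spline(Curve3D(doubled), "periodic", 10)
    radii = np.linalg.norm(dense.points - [0, 0, 3000], axis=1)
    assert np.max(np.abs(radii - 400.0)) < 1.0


def test_spline_needs_four_distinct_points():
    pts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 0, 0], [0, 0, 0.0]])
    with pytest.raises(ValidationError):
        close_curve_spline(Curve3D(pts), "periodic", 10)


# ---------------------------------------------------------- polyline length
def test_polyline_unit_square_perimeter():
    sq = Curve3D(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]]),
                 closed=True)
    assert polyline_length(sq) == pytest.approx(4.0)


def test_polyline_circle_circumference():
    pts = _circle_points(1000, r=500.0)
    c = Curve3D(pts, closed=True)
    assert polyline_length(c) == pytest.approx(2 * np.pi * 500.0, rel=1e-4)


def test_polyline_invariant_under_rigid_motion(rng):
    pts = rng.normal(0, 300, (50, 3))
    base = polyline_length(Curve3D(pts, closed=True))
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    moved = pts @ R.T + np.array([123.0, -456.0, 789.0])
    assert polyline_length(Curve3D(moved, closed=True)) == pytest.approx(
        base, rel=1e-9)


# --------------------------------------------------------- surface profile
def test_profile_points_lie_on_cylinder_surface(cylinder_scene, K, pose):
    model, img, kps = cylinder_scene
    wk = bv.localize_keypoints(img, kps, K)
    prof = sample_surface_profile(
        img, wk.pixels["Chest1"], wk.pixels["Chest2"], 50, K, wk.reference)
    axis = np.array([pose.height - model.axis_height, pose.distance])
    dist = np.hypot(prof.points[:, 1] - axis[0], prof.points[:, 2] - axis[1])
    assert np.max(np.abs(dist - 350.0)) < 2.0


def test_profile_on_flat_wall_is_straight_segment(K):
    img = DepthImage(np.full((720, 1280), 3000, dtype=np.int64))
    prof = sample_surface_profile(img, (640, 200), (640, 500), 30, K, 3000.0)
    assert np.all(prof.points[:, 2] == 3000.0)
    assert np.ptp(prof.points[:, 0]) < 1e-9  # constant X: vertical segment


def test_profile_survives_a_dropout_hole(cylinder_scene, K):
    model, img, kps = cylinder_scene
    wk = bv.localize_keypoints(img, kps, K)
    vals = img.values.copy()
    u1, v1 = wk.pixels["Chest1"]
    u2, v2 = wk.pixels["Chest2"]
    um, vm = int((u1 + u2) / 2), int((v1 + v2) / 2)
    vals[vm - 2: vm + 3, um - 2: um + 3] = 0
    prof = sample_surface_profile(
        DepthImage(vals), wk.pixels["Chest1"], wk.pixels["Chest2"],
        50, K, wk.reference)
    assert np.all(prof.points[:, 2] > 0)
    assert len(prof) >= 47


def test_profile_with_too_few_valid_samples_errors(K):
    img = DepthImage(np.zeros((720, 1280), dtype=np.int64))
    with pytest.raises(InsufficientProfileError):
        sample_surface_profile(img, (600, 200), (600, 500), 20, K, 3000.0)


# ------------------------------------------------------------- chest girth
def test_chord_mode_degenerates_to_twice_the_chord_with_warning(
        default_scene, K):
    _, img, kps = default_scene
    wk = bv.localize_keypoints(img, kps, K)
    chord = bv.euclidean_distance(wk.points["Chest1"], wk.points["Chest2"])
    with pytest.warns(UserWarning, match="chord"):
        girth = bv.chest_girth(img, kps, K,
                               gconf=GirthConfig(profile_mode="chord"), wk=wk)
    assert girth == pytest.approx(2 * chord / 10.0, rel=0.05)


def test_surface_girth_matches_twice_the_visible_arc(default_scene, K):
    model, img, kps = default_scene
    girth = bv.chest_girth(img, kps, K)
    oracle = 2.0 * bv.chest_anchor_arc(model) / 10.0
    assert girth == pytest.approx(oracle, rel=0.03)
    # and the mirrored completion can never exceed what the camera sees
    assert girth < 2.0 * bv.visible_flank_arc(model) / 10.0 * 1.02


def test_girth_strictly_increasing_in_torso_radius(pose, K):
    girths = []
    for r in (320.0, 360.0, 400.0):
        m = bv.build_cattle_model(torso_semi_depth=r, torso_semi_height=r)
        img = bv.render_depth(m, pose, K)
        kps = bv.ground_truth_keypoints(m, pose, K, img=img)
        girths.append(bv.chest_girth(img, kps, K))
    assert girths[0] < girths[1] < girths[2]
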