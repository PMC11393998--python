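"""Synthetic cattle depth scenes with analytic ground truth.

The generator stands in for live animals: a parametric geometric cow is
rendered through the same pinhole model the measurement pipeline inverts, so
every stage of the pipeline can be tested against closed-form truth.

**Geometry.**  The world frame has the ground plane at y = 0 (y up), the
body axis along x, and z pointing toward the camera.  The torso is an
elliptical cylinder (semi-axis ``torso_semi_depth`` along z, i.e. the
half-width of the chest seen from above; ``torso_semi_height`` along y)
whose axis sits ``axis_height`` above the ground; four vertical circular
cylinders are the legs; the ground is an infinite plane.  The camera sits
at ``(lateral, height, distance)`` looking along -z, axis-parallel to the
flank, exactly the tripod side-view geometry of a field recording (camera
about 1 m high, 1-5 m from the animal).

**Landmark anchors.**  Anchors are placed where an annotator clicks in a
side-view image, which for topline and chest landmarks is the torso
*silhouette* — the line where the viewing ray is tangent to the flank —
not the geometric extreme of the section (under perspective the geometric
top of a convex body is self-occluded).  Tangency is solved for the
canonical observation geometry (``view_height``, ``view_distance``,
``view_fy``/``view_cy``) baked into the model, and the anchor is snapped
onto the surface along the ray through the centre of the first visible
pixel row — the pixel an annotator actually marks — making every anchor
exactly visible: its rendered depth equals its true depth up to
quantization.  Shoulder and Pin sit on the nearest line of the flank;
Sole on the ground-contact line of the near front leg.

**Truth.**  Body height and length are anchor distances; lumbar height is
the Lumbar anchor's height above ground; the true chest girth is the
perimeter of the torso ellipse by adaptive quadrature.  The helper
:func:`visible_flank_arc` gives the arc length of the flank a camera
actually sees between the two tangency points — the analytic oracle for
what a single-view mirrored completion can recover.

**Noise.**  Depth-sensor defects are emulated by seeded pixel dropout,
blob-shaped holes, and additive Gaussian depth jitter clamped to the valid
range — the depth-domain analogue of adverse-weather robustness studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import integrate

from .camera import CameraIntrinsics, world_to_pixel
from .depth import DepthImage
from .errors import PoseError, ValidationError
from .keypoints import LANDMARKS, Keypoint, KeypointSet
from .measure import MeasurementResult

__all__ = [
    "CattleModel",
    "CameraPose",
    "NoiseSpec",
    "DEFAULT_INTRINSICS",
    "build_cattle_model",
    "random_model",
    "true_dimensions",
    "render_depth",
    "ground_truth_keypoints",
    "inject_depth_noise",
    "dropout_near_keypoints",
    "ellipse_perimeter",
    "ramanujan_perimeter",
    "visible_flank_arc",
    "chest_anchor_arc",
]

#: Synthetic camera used throughout: 1280x720, fx = fy = 700 px.  This is a
#: plausible depth-camera geometry, not any physical device's calibration.
DEFAULT_INTRINSICS = CameraIntrinsics(fx=700.0, fy=700.0, cx=640.0, cy=360.0,
                                      width=1280, height=720)


@dataclass(frozen=True)
class CameraPose:
    """Side-view camera position in the world frame (mm).

    ``distance`` is measured to the animal's centre plane (z = 0); the
    near flank is ``distance - torso_semi_depth`` away.  ``height`` is the
    optical centre above ground; ``lateral`` shifts the camera along the
    body axis.
    """

    distance: float = 3000.0
    height: float = 1000.0
    lateral: float = 0.0

    def world_to_camera(self, pts: np.ndarray) -> np.ndarray:
        """Rigid transform world (x, y, z) -> camera (X right, Y down, Z out)."""
        pts = np.asarray(pts, dtype=float)
        out = np.empty_like(pts)
        out[..., 0] = pts[..., 0] - self.lateral
        out[..., 1] = self.height - pts[..., 1]
        out[..., 2] = self.distance - pts[..., 2]
        return out


@dataclass(frozen=True)
class CattleModel:
    """Parametric cow with landmark anchors and analytic dimensions (mm).

    Built by :func:`build_cattle_model`; ``anchors`` maps each landmark
    name to its world-frame position.
    """

    torso_length: float
    torso_semi_depth: float   # half chest width along z (toward camera)
    torso_semi_height: float  # half chest height along y
    axis_height: float        # torso axis above ground
    leg_radius: float
    leg_sep: float            # |z| of each leg axis
    leg_inset: float          # leg axis distance from the torso end
    girth_offset: float       # girth plane behind the front-leg plane
    end_inset: float          # Shoulder/Pin inset from the torso ends
    withers_offset: float
    view_height: float        # canonical observation geometry for anchors
    view_distance: float
    view_fy: float            # row focal length / principal row of the
    view_cy: float            # canonical annotation view
    anchors: Dict[str, np.ndarray] = field(default_factory=dict, compare=False)

    @property
    def leg_positions(self) -> Tuple[Tuple[float, float], ...]:
        """(x, z) of the four leg axes: near/far front, near/far rear."""
        xf = -(self.torso_length / 2.0 - self.leg_inset)
        xr = +(self.torso_length / 2.0 - self.leg_inset)
        s = self.leg_sep
        return ((xf, s), (xf, -s), (xr, s), (xr, -s))


def _tangency_angles(b_v: float, b_h: float, axis_height: float,
                     cam_height: float, cam_distance: float) -> Tuple[float, float]:
    """Parameter angles (upper, lower) where rays from the camera graze the
    torso ellipse.

    The section point is P(phi) = (axis_height + b_v sin(phi), b_h cos(phi))
    in (y, z); the tangency condition from camera (h, D) reduces to
    ``A sin(phi) + B cos(phi) = C0`` with A = b_h (h - H), B = D b_v,
    C0 = b_h b_v.
    """
    A = b_h * (cam_height - axis_height)
    B = cam_distance * b_v
    C0 = b_h * b_v
    R = math.hypot(A, B)
    if C0 >= R:
        raise PoseError("camera lies inside (or on) the torso section")
    phi0 = math.atan2(A, B)
    spread = math.acos(C0 / R)
    phi_a, phi_b = phi0 + spread, phi0 - spread
    # upper tangency has the larger y = H + b_v sin(phi)
    if math.sin(phi_a) >= math.sin(phi_b):
        return phi_a, phi_b
    return phi_b, phi_a


def _row_ray_hit(b_v: float, b_h: float, axis_height: float,
                 cam_height: float, cam_distance: float,
                 fy: float, cy: float, v_row: float):
    """(y, z) world coordinates of the nearest torso-section point on the
    ray through image row ``v_row`` (pixel centre), or None on a miss."""
    dy = (v_row - cy) / fy
    Y0 = cam_height - axis_height
    Z0 = cam_distance
    A = dy ** 2 / b_v ** 2 + 1.0 / b_h ** 2
    B = -2.0 * (dy * Y0 / b_v ** 2 + Z0 / b_h ** 2)
    C = Y0 ** 2 / b_v ** 2 + Z0 ** 2 / b_h ** 2 - 1.0
    disc = B ** 2 - 4.0 * A * C
    if disc <= 0:
        return None
    t1 = (-B - math.sqrt(disc)) / (2.0 * A)
    if t1 <= 0:
        return None
    return cam_height - t1 * dy, cam_distance - t1


def build_cattle_model(
    torso_length: float = 1500.0,
    torso_semi_depth: float = 450.0,
    torso_semi_height: float = 350.0,
    axis_height: float = 900.0,
    leg_radius: float = 60.0,
    leg_sep: float = 100.0,
    leg_inset: float = 150.0,
    girth_offset: float = 150.0,
    end_inset: float = 50.0,
    withers_offset: float = 0.0,
    view_height: float = 1000.0,
    view_distance: float = 3000.0,
    view_fy: float = DEFAULT_INTRINSICS.fy,
    view_cy: float = DEFAULT_INTRINSICS.cy,
) -> CattleModel:
    """Validate dimensions and place the seven landmark anchors.

    Default dimensions describe a medium adult animal: 1.5 m torso, chest
    section 900 x 700 mm, withers about 1.25 m — squarely inside the range
    manual measurement tables report for beef cattle.
    """
    problems = []
    for name, val in [("torso_length", torso_length),
                      ("torso_semi_depth", torso_semi_depth),
                      ("torso_semi_height", torso_semi_height),
                      ("axis_height", axis_height),
                      ("leg_radius", leg_radius),
                      ("view_height", view_height),
                      ("view_distance", view_distance)]:
        if not val > 0:
            problems.append(f"{name} must be > 0, got {val}")
    if axis_height - torso_semi_height <= 0:
        problems.append("torso bottom is below the ground plane")
    if leg_sep + leg_radius > torso_semi_depth:
        problems.append("legs protrude beyond the torso flank")
    if leg_inset >= torso_length / 2:
        problems.append("leg_inset exceeds the half torso length")
    if end_inset >= torso_length / 2:
        problems.append("end_inset exceeds the half torso length")
    if view_distance <= torso_semi_depth:
        problems.append("canonical view distance is inside the torso")
    if withers_offset < 0:
        problems.append("withers_offset must be >= 0")
    if problems:
        raise ValidationError("; ".join(problems))

    phi_up, phi_low = _tangency_angles(
        torso_semi_height, torso_semi_depth, axis_height,
        view_height, view_distance)

    def _snap(phi: float, downward: bool):
        """Surface point on the ray through the outermost visible pixel
        row at the silhouette — where an annotator clicks."""
        y_t = axis_height + torso_semi_height * math.sin(phi)
        z_t = torso_semi_depth * math.cos(phi)
        v_star = view_cy + view_fy * (view_height - y_t) / (view_distance - z_t)
        v_row = math.ceil(v_star) if downward else math.floor(v_star)
        step = 1 if downward else -1
        for _ in range(3):  # guard against a grazing-ray numerical miss
            hit = _row_ray_hit(torso_semi_height, torso_semi_depth,
                               axis_height, view_height, view_distance,
                               view_fy, view_cy, v_row)
            if hit is not None:
                return hit
            v_row += step
        raise ValidationError("silhouette row snapping failed; the torso "
                              "spans less than one pixel in this view")

    y_up, z_up = _snap(phi_up, downward=True)     # topline: first row below
    y_low, z_low = _snap(phi_low, downward=False)  # belly: last row above

    x_front = -(torso_length / 2.0 - leg_inset)
    x_rear = +(torso_length / 2.0 - leg_inset)
    x_girth = x_front + girth_offset
    x_lumbar = x_rear - 250.0
    x_shoulder = -(torso_length / 2.0 - end_inset)
    x_pin = +(torso_length / 2.0 - end_inset)

    anchors = {
        "Withers": np.array([x_front, y_up + withers_offset, z_up]),
        "Sole": np.array([x_front, 0.0, leg_sep + leg_radius]),
        "Shoulder": np.array([x_shoulder, axis_height, torso_semi_depth]),
        "Pin": np.array([x_pin, axis_height, torso_semi_depth]),
        "Chest1": np.array([x_girth, y_up, z_up]),
        "Chest2": np.array([x_girth, y_low, z_low]),
        "Lumbar": np.array([x_lumbar, y_up, z_up]),
    }
    return CattleModel(
        torso_length=torso_length, torso_semi_depth=torso_semi_depth,
        torso_semi_height=torso_semi_height, axis_height=axis_height,
        leg_radius=leg_radius, leg_sep=leg_sep, leg_inset=leg_inset,
        girth_offset=girth_offset, end_inset=end_inset,
        withers_offset=withers_offset, view_height=view_height,
        view_distance=view_distance, view_fy=view_fy, view_cy=view_cy,
        anchors=anchors,
    )


def random_model(rng: np.random.Generator, **overrides) -> CattleModel:
    """Draw a plausible adult animal: withers 1.08-1.27 m, torso
    1.35-1.65 m, chest section 760-940 x 600-760 mm."""
    params = dict(
        torso_length=rng.uniform(1350.0, 1650.0),
        axis_height=rng.uniform(780.0, 900.0),
        torso_semi_depth=rng.uniform(380.0, 470.0),
        leg_radius=rng.uniform(50.0, 70.0),
    )
    params["torso_semi_height"] = rng.uniform(
        300.0, min(380.0, 1270.0 - params["axis_height"]))
    params.update(overrides)
    return build_cattle_model(**params)


# ------------------------------------------------------------------- truth
def ellipse_perimeter(a: float, b: float) -> float:
    """Perimeter of an ellipse with semi-axes a, b by adaptive quadrature
    of the arc-length integrand, accurate to ~1e-9 relative."""
    if a < 0 or b < 0:
        raise ValidationError("semi-axes must be non-negative")
    val, _ = integrate.quad(
        lambda th: math.hypot(a * math.sin(th), b * math.cos(th)),
        0.0, 2.0 * math.pi, epsabs=1e-10, epsrel=1e-12, limit=200)
    return val


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's second ellipse-perimeter approximation (cross-check)."""
    if a + b == 0:
        return 0.0
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def true_dimensions(m: CattleModel) -> MeasurementResult:
    """Analytic ground truth for the four dimensions, in cm."""
    a = m.anchors
    return MeasurementResult(
        body_height_cm=float(np.linalg.norm(a["Withers"] - a["Sole"])) / 10.0,
        body_length_cm=float(np.linalg.norm(a["Shoulder"] - a["Pin"])) / 10.0,
        lumbar_height_cm=float(a["Lumbar"][1]) / 10.0,
        chest_girth_cm=ellipse_perimeter(m.torso_semi_depth,
                                         m.torso_semi_height) / 10.0,
    )


def _section_angle(m: CattleModel, point_yz: Tuple[float, float]) -> float:
    """Parameter angle of a point on the torso section ellipse."""
    y, z = point_yz
    return math.atan2((y - m.axis_height) / m.torso_semi_height,
                      z / m.torso_semi_depth)


def _section_arc(m: CattleModel, phi_from: float, phi_to: float) -> float:
    b_v, b_h = m.torso_semi_height, m.torso_semi_depth
    val, _ = integrate.quad(
        lambda ph: math.hypot(b_v * math.cos(ph), b_h * math.sin(ph)),
        phi_from, phi_to, epsabs=1e-9, epsrel=1e-10, limit=200)
    return val


def visible_flank_arc(m: CattleModel, pose: Optional[CameraPose] = None) -> float:
    """Arc length (mm) of the torso section between the two tangency
    points seen from ``pose`` (canonical view when omitted).

    A mirrored single-view completion reconstructs at most twice this arc,
    which is strictly below the full perimeter from any finite distance.
    """
    if pose is None:
        pose = CameraPose(distance=m.view_distance, height=m.view_height)
    phi_up, phi_low = _tangency_angles(
        m.torso_semi_height, m.torso_semi_depth, m.axis_height,
        pose.height, pose.distance)
    return _section_arc(m, phi_low, phi_up)


def chest_anchor_arc(m: CattleModel) -> float:
    """Arc length (mm) of the torso section between the Chest1 and Chest2
    anchors through the near flank.

    This is the portion of the section the surface profile actually spans
    (the anchors sit on the outermost *pixel rows* of the silhouette, a
    hair inside the mathematical tangency points), so twice this arc is
    the analytic oracle for the mirrored girth estimate.
    """
    phi1 = _section_angle(m, (m.anchors["Chest1"][1], m.anchors["Chest1"][2]))
    phi2 = _section_angle(m, (m.anchors["Chest2"][1], m.anchors["Chest2"][2]))
    return _section_arc(m, min(phi1, phi2), max(phi1, phi2))


# ---------------------------------------------------------------- rendering
def render_depth(
    m: CattleModel,
    pose: CameraPose = CameraPose(),
    K: CameraIntrinsics = DEFAULT_INTRINSICS,
    far: float = 7000.0,
) -> DepthImage:
    """Ray-cast the scene: per pixel, the Z-coordinate (mm, integer) of the
    nearest hit on torso, legs, or ground; 0 where nothing is hit within
    ``far``.

    Depth is the distance along the optical axis (not the ray length), so
    the pinhole inverse projection is exact on rendered maps up to the
    1 mm integer quantization.
    """
    if pose.height <= 0:
        raise PoseError("camera below the ground plane")
    if pose.distance <= m.torso_semi_depth:
        raise PoseError("camera inside the torso")
    for xl, zl in m.leg_positions:
        if math.hypot(pose.lateral - xl, pose.distance - zl) <= m.leg_radius:
            raise PoseError("camera inside a leg")

    dx = (np.arange(K.width) - K.cx) / K.fx           # (W,)
    dy = (np.arange(K.height) - K.cy) / K.fy          # (H,)
    DX = dx[None, :]
    DY = dy[:, None]
    best = np.full((K.height, K.width), np.inf)

    # ground plane y = 0  ->  camera-frame Y = pose.height
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ground = np.where(DY > 0, pose.height / DY, np.inf)
    t_ground = np.broadcast_to(t_ground, best.shape)
    best = np.minimum(best, t_ground)

    # torso: elliptical cylinder along camera X
    b_v, b_h = m.torso_semi_height, m.torso_semi_depth
    Y0 = pose.height - m.axis_height
    Z0 = pose.distance
    A = (DY / b_v) ** 2 + 1.0 / b_h ** 2
    B = -2.0 * (DY * Y0 / b_v ** 2 + Z0 / b_h ** 2)
    C = Y0 ** 2 / b_v ** 2 + Z0 ** 2 / b_h ** 2 - 1.0
    disc = B ** 2 - 4.0 * A * C
    with np.errstate(invalid="ignore"):
        t_torso = np.where(disc >= 0, (-B - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * A), np.inf)
        x_hit = t_torso * DX
    xmin = -m.torso_length / 2.0 - pose.lateral
    xmax = +m.torso_length / 2.0 - pose.lateral
    ok = (t_torso > 0) & (x_hit >= xmin) & (x_hit <= xmax)
    best = np.minimum(best, np.where(ok, t_torso, np.inf))

    # legs: circular cylinders along world y, between ground and torso axis
    for xl_w, zl_w in m.leg_positions:
        Xl = xl_w - pose.lateral
        Zl = pose.distance - zl_w
        A_l = DX ** 2 + 1.0
        B_l = -2.0 * (DX * Xl + Zl)
        C_l = Xl ** 2 + Zl ** 2 - m.leg_radius ** 2
        disc = B_l ** 2 - 4.0 * A_l * C_l
        with np.errstate(invalid="ignore"):
            t_leg = np.where(disc >= 0, (-B_l - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * A_l), np.inf)
            y_world = pose.height - t_leg * DY
        ok = (t_leg > 0) & (y_world >= 0.0) & (y_world <= m.axis_height)
        best = np.minimum(best, np.where(ok, t_leg, np.inf))

    depth = np.where(np.isfinite(best) & (best <= far), np.rint(best), 0.0)
    return DepthImage(depth.astype(np.int64))


def ground_truth_keypoints(
    m: CattleModel,
    pose: CameraPose = CameraPose(),
    K: CameraIntrinsics = DEFAULT_INTRINSICS,
    img: Optional[DepthImage] = None,
    occlusion_tol: float = 50.0,
) -> KeypointSet:
    """Project the anchors and assign COCO visibility flags.

    Visibility 2 when the projected pixel is inside the frame and the
    rendered depth there matches the anchor's depth within
    ``occlusion_tol`` mm; 1 when in frame but occluded; 0 when behind the
    camera or out of frame.  Renders the scene when ``img`` is omitted.
    """
    if img is None:
        img = render_depth(m, pose, K)
    points: Dict[str, Keypoint] = {}
    for name in LANDMARKS:
        cam = pose.world_to_camera(m.anchors[name])
        if cam[2] <= 0:
            points[name] = Keypoint(0.0, 0.0, 0)
            continue
        u, v, z = world_to_pixel(cam, K)
        iu, iv = int(round(float(u))), int(round(float(v)))
        if not (0 <= iu < K.width and 0 <= iv < K.height):
            points[name] = Keypoint(float(u), float(v), 0)
            continue
        rendered = img.at(iu, iv)
        vis = 2 if abs(rendered - z) <= occlusion_tol else 1
        points[name] = Keypoint(float(u), float(v), vis)

    # body box from the projected corners of the animal's bounding volume
    xs = (-m.torso_length / 2.0, m.torso_length / 2.0)
    ys = (0.0, m.axis_height + m.torso_semi_height + m.withers_offset)
    zs = (-m.torso_semi_depth, m.torso_semi_depth)
    corners = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    u, v, _ = world_to_pixel(pose.world_to_camera(corners), K)
    u = np.clip(u, 0, K.width - 1)
    v = np.clip(v, 0, K.height - 1)
    bbox = [float(u.min()), float(v.min()),
            float(u.max() - u.min()), float(v.max() - v.min())]
    return KeypointSet(points=points, bbox=bbox)


# -------------------------------------------------------------------- noise
@dataclass(frozen=True)
class NoiseSpec:
    """Seeded depth-sensor defects: pixel dropout, blob holes, jitter."""

    dropout_rate: float = 0.0
    jitter_sd: float = 0.0
    hole_count: int = 0
    hole_radius: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError("dropout_rate must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")
        if self.hole_count < 0 or self.hole_radius < 0:
            raise ValidationError("hole parameters must be >= 0")


def inject_depth_noise(img: DepthImage, spec: NoiseSpec,
                       far: float = 7000.0) -> DepthImage:
    """Apply the noise spec; identical seeds give bit-identical outputs."""
    rng = np.random.default_rng(spec.seed)
    vals = img.values.astype(float).copy()
    h, w = vals.shape
    if spec.hole_count > 0:
        vv, uu = np.mgrid[0:h, 0:w]
        for _ in range(spec.hole_count):
            cu = rng.uniform(0, w)
            cv = rng.uniform(0, h)
            vals[(uu - cu) ** 2 + (vv - cv) ** 2 <= spec.hole_radius ** 2] = 0.0
    if spec.dropout_rate > 0:
        vals[rng.random((h, w)) < spec.dropout_rate] = 0.0
    if spec.jitter_sd > 0:
        valid = vals > 0
        vals[valid] += rng.normal(0.0, spec.jitter_sd, int(valid.sum()))
        vals = np.clip(vals, 0.0, far)
    return DepthImage(np.rint(vals).astype(np.int64))


def dropout_near_keypoints(
    img: DepthImage,
    kps: KeypointSet,
    rate: float,
    seed: int,
    half_width: int = 15,
) -> DepthImage:
    """Zero a seeded fraction of pixels inside windows around each marked
    landmark — localized dropout stressing exactly the pixels the
    conditional filter depends on."""
    rng = np.random.default_rng(seed)
    vals = img.values.copy()
    for name in kps:
        kp = kps[name]
        if kp.visibility == 0:
            continue
        u0 = int(round(kp.u))
        v0 = int(round(kp.v))
        u_lo, u_hi = max(0, u0 - half_width), min(img.width, u0 + half_width + 1)
        v_lo, v_hi = max(0, v0 - half_width), min(img.height, v0 + half_width + 1)
        block = vals[v_lo:v_hi, u_lo:u_hi]
        mask = rng.random(block.shape) < rate
        block[mask] = 0
    return DepthImage(vals)
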