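"""The four body dimensions: body height, lumbar height, body oblique
length, and chest girth.

All landmark geometry lives in camera-frame millimetres; results are
reported in centimetres (cm = mm / 10, with no other scaling anywhere).

* **Body height** — Euclidean distance from Withers (highest point of the
  ridge between the shoulder blades) to Sole (bottom of the hoof).
* **Body oblique length** — Euclidean distance from the Shoulder endpoint
  to the Pin bone (outer edge of the tuber ischium).
* **Lumbar height** — the stick measurement is emulated by constructing a
  ground point directly beneath the Lumbar landmark: the ground pixel
  combines the Lumbar column with the Sole row, is back-projected with the
  Sole's refined depth (the camera-to-ground distance at the hoof), and the
  lumbar height is the distance from the Lumbar point to that ground point.
* **Chest girth** — the curve pipeline of :mod:`bovimetry.girth`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .camera import CameraIntrinsics, pixel_to_world
from .depth import (
    DepthFilterParams,
    DepthImage,
    WorldKeypoints,
    localize_keypoints,
)
from .errors import BovimetryError, OutOfBoundsError
from .girth import (
    Curve3D,
    GirthConfig,
    close_curve_spline,
    generate_intermediate_points,
    mirror_half_curve,
    polyline_length,
    rbf_smooth_curve,
    sample_surface_profile,
)
from .keypoints import KeypointSet

__all__ = [
    "MeasurementResult",
    "euclidean_distance",
    "body_height",
    "body_length",
    "lumbar_height",
    "chest_girth",
    "measure_animal",
]

MEASUREMENT_NAMES = ("body_height_cm", "lumbar_height_cm",
                     "body_length_cm", "chest_girth_cm")


@dataclass
class MeasurementResult:
    """The four dimensions (cm) plus an audit trail.

    Dimensions that could not be computed are ``None`` (never zero); the
    reason is recorded in ``errors`` under the measurement name.
    """

    body_height_cm: Optional[float] = None
    lumbar_height_cm: Optional[float] = None
    body_length_cm: Optional[float] = None
    chest_girth_cm: Optional[float] = None
    refined_depths_mm: Dict[str, float] = field(default_factory=dict)
    reference_depth_mm: Optional[float] = None
    errors: Dict[str, str] = field(default_factory=dict)

    def as_row(self) -> Dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in MEASUREMENT_NAMES}


def euclidean_distance(a, b) -> float:
    """Distance in mm between two camera-frame points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.sum((a - b) ** 2)))


def body_height(wk: WorldKeypoints) -> float:
    """Withers-to-Sole spatial length, cm."""
    wk.require("Withers", "Sole")
    return euclidean_distance(wk.points["Withers"], wk.points["Sole"]) / 10.0


def body_length(wk: WorldKeypoints) -> float:
    """Shoulder-to-Pin spatial length (body oblique length), cm."""
    wk.require("Shoulder", "Pin")
    return euclidean_distance(wk.points["Shoulder"], wk.points["Pin"]) / 10.0


def lumbar_height(
    wk: WorldKeypoints,
    img: DepthImage,
    K: CameraIntrinsics,
    params: DepthFilterParams = DepthFilterParams(),
) -> float:
    """Height of the Lumbar point above the ground, cm.

    The ground point takes the Lumbar column, the Sole row, and the Sole's
    refined depth, landing on the ground plane directly beneath the loin.
    """
    wk.require("Lumbar", "Sole")
    u_l, _ = wk.pixels["Lumbar"]
    _, v_s = wk.pixels["Sole"]
    if not (0 <= u_l < img.width and 0 <= v_s < img.height):
        raise OutOfBoundsError(
            f"constructed ground pixel ({u_l:.1f}, {v_s:.1f}) outside the image")
    ground = pixel_to_world(u_l, v_s, wk.depths["Sole"], K)
    return euclidean_distance(wk.points["Lumbar"], ground) / 10.0


def chest_girth(
    img: DepthImage,
    kps: KeypointSet,
    K: CameraIntrinsics,
    dparams: DepthFilterParams = DepthFilterParams(),
    gconf: GirthConfig = GirthConfig(),
    wk: Optional[WorldKeypoints] = None,
) -> float:
    """Chest girth in cm via profile -> RBF smoothing -> mirror -> closed
    B-spline -> arc length.

    ``wk`` may carry pre-localized keypoints to avoid recomputing the
    reference depth; otherwise :func:`localize_keypoints` runs internally.
    """
    if wk is None:
        wk = localize_keypoints(img, kps, K, dparams)
    wk.require("Chest1", "Chest2")
    c1 = wk.points["Chest1"]
    c2 = wk.points["Chest2"]

    if gconf.profile_mode == "surface":
        profile = sample_surface_profile(
            img, wk.pixels["Chest1"], wk.pixels["Chest2"],
            gconf.num_points, K, wk.reference, dparams)
    else:
        warnings.warn(
            "chord profile mode: the girth degenerates to a flat loop of "
            "about twice the Chest1-Chest2 distance", stacklevel=2)
        profile = generate_intermediate_points(c1, c2, gconf.num_points)

    smoothed = rbf_smooth_curve(profile, gconf.smooth_factor,
                                gconf.refine_factor, gconf.rbf_epsilon)
    mirrored = mirror_half_curve(smoothed, c1, c2, frame=gconf.mirror_frame)
    loop = Curve3D(np.vstack([smoothed.points, mirrored.points]))
    closed = close_curve_spline(loop, gconf.spline_closure, gconf.refine_factor)
    return polyline_length(closed) / 10.0


def measure_animal(
    img: DepthImage,
    kps: KeypointSet,
    K: CameraIntrinsics,
    dparams: DepthFilterParams = DepthFilterParams(),
    gconf: GirthConfig = GirthConfig(),
) -> MeasurementResult:
    """Compute all four dimensions, collecting per-dimension failures.

    The reference depth is mandatory (its absence is a pipeline error and
    propagates); a missing landmark only blanks the dimensions that need
    it, so partial results survive.
    """
    wk = localize_keypoints(img, kps, K, dparams)
    result = MeasurementResult(
        refined_depths_mm=dict(wk.depths),
        reference_depth_mm=wk.reference,
    )
    stages = {
        "body_height_cm": lambda: body_height(wk),
        "lumbar_height_cm": lambda: lumbar_height(wk, img, K, dparams),
        "body_length_cm": lambda: body_length(wk),
        "chest_girth_cm": lambda: chest_girth(img, kps, K, dparams, gconf, wk=wk),
    }
    for name, fn in stages.items():
        try:
            setattr(result, name, fn())
        except BovimetryError as exc:
            result.errors[name] = f"{type(exc).__name__}: {exc}"
    return result
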