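"""Depth-image handling and conditional keypoint depth refinement.

A raw depth frame stores integer millimetres in 16-bit samples; 0 encodes
"no measurement" (sensor dropout, out of range).  A landmark detected in the
RGB image rarely lands on a reliable depth pixel, so each keypoint's depth is
*refined* before back-projection:

1.  A **reference depth** is taken as the mean of valid samples
    (``valid_min < d <= valid_max``, default (0, 7000] mm) in a 3x3 window
    around the midpoint of the Shoulder and Pin landmarks — a stable patch on
    the animal's flank.
2.  Each keypoint then receives the depth of the nearest pixel (growing
    Chebyshev rings, up to ``max_radius``) whose value is valid *and* within
    ``ref_tolerance`` (default 500 mm) of the reference; this rejects
    background and foreground clutter around body-contour landmarks.
3.  The refined depth and the (sub-pixel) keypoint coordinates are lifted to
    camera-frame 3-D coordinates through the pinhole inverse projection.

The default ring search honors "nearest valid depth"; a ``raster`` mode is
retained that scans the square window in dx-major order and returns the
first hit, for parity with naive double-loop implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from PIL import Image

from .camera import CameraIntrinsics, pixel_to_world
from .errors import (
    DepthLoadError,
    MissingLandmarkError,
    NoReferenceDepthError,
    OutOfBoundsError,
    ValidationError,
)
from .keypoints import Keypoint, KeypointSet

__all__ = [
    "DepthImage",
    "DepthFilterParams",
    "WorldKeypoints",
    "load_depth_image",
    "save_depth_image",
    "reference_depth",
    "find_nearest_valid_depth",
    "localize_keypoints",
]


@dataclass
class DepthImage:
    """A 2-D grid of depths in integer millimetres; 0 = no measurement."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValidationError(f"depth image must be a non-empty 2-D grid, got shape {v.shape}")
        if np.any(v < 0):
            raise ValidationError("depth image contains negative values")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def in_bounds(self, u: int, v: int) -> bool:
        return 0 <= u < self.width and 0 <= v < self.height

    def at(self, u: int, v: int) -> int:
        """Depth at integer pixel (column u, row v)."""
        return int(self.values[v, u])


@dataclass(frozen=True)
class DepthFilterParams:
    """Tunable parameters of the conditional depth filter (all mm / px).

    ``neighborhood`` is the half-width of the reference window (1 -> 3x3).
    ``search`` selects "ring" (nearest-first, default) or "raster"
    (dx-major square scan) candidate ordering.  ``grow_reference`` doubles
    the reference window half-width up to three times when the initial
    window holds no valid sample.
    """

    valid_min: float = 0.0
    valid_max: float = 7000.0
    ref_tolerance: float = 500.0
    neighborhood: int = 1
    max_radius: int = 20
    search: str = "ring"
    grow_reference: bool = False

    def __post_init__(self) -> None:
        problems = []
        if not 0 <= self.valid_min < self.valid_max:
            problems.append("need 0 <= valid_min < valid_max")
        if not self.ref_tolerance > 0:
            problems.append("ref_tolerance must be > 0")
        if self.max_radius < 1:
            problems.append("max_radius must be >= 1")
        if self.neighborhood < 1:
            problems.append("neighborhood must be >= 1")
        if self.search not in ("ring", "raster"):
            problems.append(f"unknown search mode {self.search!r}")
        if problems:
            raise ValidationError("; ".join(problems))

    def is_valid(self, depth: float) -> bool:
        return self.valid_min < depth <= self.valid_max


@dataclass
class WorldKeypoints:
    """Landmarks lifted to 3-D camera coordinates (mm).

    ``points`` holds (X, Y, Z) per landmark; ``depths`` the refined depth
    used; ``pixels`` the original (sub-pixel) image coordinates; ``missing``
    the landmarks for which no valid depth was found within the search
    radius (they are *absent*, never fabricated).
    """

    points: Dict[str, np.ndarray] = field(default_factory=dict)
    depths: Dict[str, float] = field(default_factory=dict)
    pixels: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    reference: float = 0.0
    missing: Tuple[str, ...] = ()

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, *names: str) -> None:
        """Raise :class:`MissingLandmarkError` for the first absent name."""
        for name in names:
            if name not in self.points:
                reason = ("no valid depth within search radius"
                          if name in self.missing else "not provided")
                raise MissingLandmarkError(name, reason)


# --------------------------------------------------------------------- IO
def load_depth_image(path: str | Path) -> DepthImage:
    """Read a depth image; 16-bit sample values are millimetres.

    Accepts single-channel 8/16-bit PNGs (the native storage) and
    multi-channel images, from which channel 0 is taken.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError as exc:
        raise DepthLoadError(f"depth image not found: {path}") from exc
    except Exception as exc:  # undecodable file
        raise DepthLoadError(f"cannot decode depth image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.ndim != 2 or arr.size == 0:
        raise DepthLoadError(f"depth image {path} has unusable shape {arr.shape}")
    return DepthImage(arr.astype(np.int64))


def save_depth_image(img: DepthImage, path: str | Path) -> None:
    """Write a depth grid as a 16-bit grayscale PNG (1 sample = 1 mm)."""
    arr = np.asarray(img.values)
    if np.any(arr > np.iinfo(np.uint16).max):
        raise ValidationError("depth values exceed 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(path)


# ------------------------------------------------------------ reference depth
def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (symmetric)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reference_depth(
    img: DepthImage,
    shoulder: Tuple[float, float],
    pin: Tuple[float, float],
    params: DepthFilterParams = DepthFilterParams(),
) -> float:
    """Benchmark depth: mean of valid samples in a window around the
    Shoulder-Pin midpoint.

    The midpoint is rounded half-away-from-zero to integer pixels; the full
    ``(2*neighborhood+1)``-square window must lie inside the image.  With
    ``grow_reference`` the half-width doubles up to three times before
    giving up.
    """
    mu = _round_half_away((shoulder[0] + pin[0]) / 2.0)
    mv = _round_half_away((shoulder[1] + pin[1]) / 2.0)
    half = params.neighborhood
    attempts = 4 if params.grow_reference else 1
    for _ in range(attempts):
        if not (half <= mu < img.width - half and half <= mv < img.height - half):
            raise OutOfBoundsError(
                f"reference window (half-width {half}) around midpoint "
                f"({mu}, {mv}) exceeds the {img.width}x{img.height} image")
        window = img.values[mv - half: mv + half + 1, mu - half: mu + half + 1]
        valid = window[(window > params.valid_min) & (window <= params.valid_max)]
        if valid.size:
            return float(valid.mean())
        half *= 2
    raise NoReferenceDepthError(
        f"no valid depth in the reference window around midpoint ({mu}, {mv})")


# ------------------------------------------------------- conditional filtering
def _ring_offsets(radius: int):
    """Chebyshev ring at ``radius``, ordered by (dy, dx) ascending."""
    if radius == 0:
        yield (0, 0)
        return
    for dy in range(-radius, radius + 1):
        if abs(dy) == radius:
            for dx in range(-radius, radius + 1):
                yield (dy, dx)
        else:
            yield (dy, -radius)
            yield (dy, radius)


def find_nearest_valid_depth(
    img: DepthImage,
    p: Tuple[float, float],
    ref: float,
    params: DepthFilterParams = DepthFilterParams(),
) -> Optional[float]:
    """Nearest depth around pixel ``p`` that is valid and close to ``ref``.

    A candidate qualifies when ``valid_min < d <= valid_max`` and
    ``|d - ref| <= ref_tolerance``.  In ``ring`` mode candidates are visited
    on concentric Chebyshev rings of increasing radius (ties broken by scan
    order within a ring), so the returned pixel is at minimal ring distance.
    In ``raster`` mode the square window is scanned dx-major and the first
    qualifying value wins.  Returns None when nothing qualifies within
    ``max_radius``; off-image candidates are skipped silently.
    """
    u0 = _round_half_away(p[0])
    v0 = _round_half_away(p[1])
    if not img.in_bounds(u0, v0):
        raise OutOfBoundsError(f"pixel ({u0}, {v0}) outside the image")
    if ref <= 0:
        raise ValidationError(f"reference depth must be positive, got {ref}")

    def qualifies(u: int, v: int) -> Optional[float]:
        if not img.in_bounds(u, v):
            return None
        d = float(img.values[v, u])
        if params.is_valid(d) and abs(d - ref) <= params.ref_tolerance:
            return d
        return None

    if params.search == "raster":
        r = params.max_radius
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                d = qualifies(u0 + dx, v0 + dy)
                if d is not None:
                    return d
        return None

    for radius in range(params.max_radius + 1):
        for dy, dx in _ring_offsets(radius):
            d = qualifies(u0 + dx, v0 + dy)
            if d is not None:
                return d
    return None


# ---------------------------------------------------------------- keypoints
def localize_keypoints(
    img: DepthImage,
    kps: KeypointSet,
    K: CameraIntrinsics,
    params: DepthFilterParams = DepthFilterParams(),
) -> WorldKeypoints:
    """Refine every marked keypoint's depth and lift it to 3-D.

    Shoulder and Pin must be marked (visibility > 0): their midpoint anchors
    the reference depth.  Each marked landmark gets the conditionally
    filtered depth from :func:`find_nearest_valid_depth`; landmarks with no
    qualifying depth are recorded in ``missing``.  Back-projection uses the
    original sub-pixel coordinates with the refined depth.
    """
    for needed in ("Shoulder", "Pin"):
        if not kps.visible(needed):
            raise MissingLandmarkError(
                needed, "required for the reference depth midpoint")
    sh, pin = kps["Shoulder"], kps["Pin"]
    try:
        ref = reference_depth(img, (sh.u, sh.v), (pin.u, pin.v), params)
    except NoReferenceDepthError as exc:
        raise NoReferenceDepthError(
            f"Shoulder-Pin midpoint reference failed: {exc}") from exc

    wk = WorldKeypoints(reference=ref)
    missing = []
    for name in kps:
        kp: Keypoint = kps[name]
        if kp.visibility == 0:
            continue
        iu, iv = _round_half_away(kp.u), _round_half_away(kp.v)
        if not img.in_bounds(iu, iv):
            raise OutOfBoundsError(
                f"landmark {name!r} at ({kp.u:.1f}, {kp.v:.1f}) outside the image")
        depth = find_nearest_valid_depth(img, (kp.u, kp.v), ref, params)
        if depth is None:
            missing.append(name)
            continue
        wk.points[name] = pixel_to_world(kp.u, kp.v, depth, K)
        wk.depths[name] = depth
        wk.pixels[name] = (kp.u, kp.v)
    wk.missing = tuple(missing)
    return wk
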