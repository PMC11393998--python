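"""Pinhole camera model: pixel+depth <-> 3-D camera-frame coordinates.

The camera frame follows the image-indexing convention: pixel ``(u, v)`` is
``(column, row)`` with the origin at the top-left, X points right, Y points
*down*, and Z runs along the optical axis away from the camera.  With zero
skew the intrinsic matrix

    K = [[fx, 0, cx],
         [0, fy, cy],
         [0,  0,  1]]

maps a camera-frame point ``(X, Y, Z)`` to the pixel ``Z [u, v, 1]^T = K
[X, Y, Z]^T``; because K is upper-triangular with zero skew the inverse is
closed-form and exact:

    X = (u - cx) * Z / fx,   Y = (v - cy) * Z / fy.

Depth is the Z-coordinate along the optical axis in millimetres (not the ray
length), which is the convention rectified depth cameras emit.  No lens
distortion model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import BehindCameraError, InvalidDepthError, ValidationError

__all__ = ["CameraIntrinsics", "pixel_to_world", "world_to_pixel"]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters, all in pixels.

    Attributes
    ----------
    fx, fy : float
        Focal lengths along the image x (column) and y (row) axes.
    cx, cy : float
        Principal point (column, row).
    width, height : int
        Image size in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        problems = []
        if not self.fx > 0:
            problems.append(f"fx must be > 0, got {self.fx}")
        if not self.fy > 0:
            problems.append(f"fy must be > 0, got {self.fy}")
        if not 0 <= self.cx < self.width:
            problems.append(f"cx={self.cx} outside [0, width={self.width})")
        if not 0 <= self.cy < self.height:
            problems.append(f"cy={self.cy} outside [0, height={self.height})")
        if problems:
            raise ValidationError("; ".join(problems))

    @classmethod
    def from_file(cls, path: str | Path) -> "CameraIntrinsics":
        """Load intrinsics from a flat YAML/JSON key-value file.

        All six keys (fx, fy, cx, cy, width, height) are required; a physical
        camera has no sensible defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"intrinsics file {path} is not a mapping")
        missing = [k for k in ("fx", "fy", "cx", "cy", "width", "height") if k not in raw]
        if missing:
            raise ValidationError(f"intrinsics file {path} missing keys: {missing}")
        return cls(
            fx=float(raw["fx"]), fy=float(raw["fy"]),
            cx=float(raw["cx"]), cy=float(raw["cy"]),
            width=int(raw["width"]), height=int(raw["height"]),
        )

    def to_dict(self) -> dict:
        return {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
                "width": self.width, "height": self.height}


def pixel_to_world(u, v, depth, K: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel coordinates and depth to camera-frame mm.

    Parameters
    ----------
    u, v : float or array
        Pixel coordinates (column, row); sub-pixel values are allowed.
    depth : float or array, mm
        Depth along the optical axis; must be strictly positive.
    K : CameraIntrinsics

    Returns
    -------
    ndarray, shape (..., 3)
        Camera-frame coordinates (X, Y, Z) in mm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise InvalidDepthError(f"non-positive depth in back-projection: {depth}")
    x = (u - K.cx) * depth / K.fx
    y = (v - K.cy) * depth / K.fy
    return np.stack(np.broadcast_arrays(x, y, depth), axis=-1)


def world_to_pixel(point, K: CameraIntrinsics):
    """Project camera-frame point(s) (mm) to pixel coordinates and depth.

    Returns ``(u, v, depth)`` where depth is the Z-coordinate.  Raises
    :class:`BehindCameraError` for any point with Z <= 0.
    """
    p = np.asarray(point, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    if np.any(z <= 0):
        raise BehindCameraError("point with Z <= 0 cannot be projected")
    u = K.fx * x / z + K.cx
    v = K.fy * y / z + K.cy
    return u, v, z
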