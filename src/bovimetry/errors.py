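"""Exception hierarchy for the measurement pipeline.

Every stage failure carries enough context (landmark or stage name) for a
caller to report *which* input was unusable, so a batch run can emit partial
results instead of dying on the first bad animal.
"""

from __future__ import annotations


class BovimetryError(Exception):
    """Base class for all pipeline errors."""


class InvalidDepthError(BovimetryError):
    """A depth value was non-positive where a valid measurement is required."""


class BehindCameraError(BovimetryError):
    """A 3-D point with Z <= 0 cannot be projected onto the image plane."""


class DepthLoadError(BovimetryError):
    """The depth image file is missing, unreadable, or empty."""


class OutOfBoundsError(BovimetryError):
    """A pixel coordinate (or derived window) falls outside the image."""


class NoReferenceDepthError(BovimetryError):
    """No valid depth sample in the reference window around the
    shoulder--pin midpoint."""


class MissingLandmarkError(BovimetryError):
    """A landmark required by a measurement is absent or has no valid depth."""

    def __init__(self, landmark: str, reason: str = "missing"):
        self.landmark = landmark
        super().__init__(f"landmark {landmark!r}: {reason}")


class DegenerateChordError(BovimetryError):
    """Chest1 and Chest2 coincide; no chord can be built."""


class InsufficientProfileError(BovimetryError):
    """Fewer than three surface-profile samples had a valid depth."""


class UndefinedMetricError(BovimetryError):
    """An evaluation metric has a zero denominator (e.g. no visible
    landmarks for OKS, or TP+FP = 0 for precision)."""


class PoseError(BovimetryError):
    """The synthetic camera pose intersects the scene geometry."""


class ValidationError(BovimetryError):
    """Model or parameter validation failed; message lists all violations."""
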