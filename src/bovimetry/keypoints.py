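"""The seven cattle body landmarks and their JSON serialization.

A side view of standing cattle is annotated with seven named landmarks:

==========  =========================================================
Withers     highest point of the ridge between the shoulder blades
Sole        bottom of the hoof at ground contact
Shoulder    shoulder endpoint (anterior end of body oblique length)
Pin         outer edge of the tuber ischium (posterior endpoint)
Chest1      rear edge of the withers, top of the girth plane
Chest2      chest base, bottom of the girth plane
Lumbar      topline point over the loin
==========  =========================================================

Visibility follows the COCO convention: 0 = unmarked, 1 = marked but
obscured, 2 = marked and visible.

Two JSON layouts are accepted: a name-keyed map

    {"image": "...", "bbox": [x, y, w, h],
     "keypoints": {"Withers": [u, v, 2], ...}}

and a COCO-compatible flat list of ordered ``[u, v, visibility]`` triples in
the fixed landmark order above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Optional, Sequence

from .errors import ValidationError

__all__ = ["LANDMARKS", "Keypoint", "KeypointSet"]

#: Canonical landmark order (also the COCO flattening order).
LANDMARKS = ("Withers", "Sole", "Shoulder", "Pin", "Chest1", "Chest2", "Lumbar")


@dataclass(frozen=True)
class Keypoint:
    """A single 2-D landmark: pixel position plus visibility flag."""

    u: float
    v: float
    visibility: int = 2

    def __post_init__(self) -> None:
        if self.visibility not in (0, 1, 2):
            raise ValidationError(f"visibility must be 0/1/2, got {self.visibility}")


@dataclass
class KeypointSet:
    """Mapping of landmark name -> :class:`Keypoint` for one animal.

    Only the seven canonical names are legal keys.  ``image`` and ``bbox``
    (x, y, w, h of the body box, used for the OKS object scale) are optional
    annotation metadata.
    """

    points: Dict[str, Keypoint] = field(default_factory=dict)
    image: Optional[str] = None
    bbox: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        unknown = set(self.points) - set(LANDMARKS)
        if unknown:
            raise ValidationError(f"unknown landmark names: {sorted(unknown)}")

    def __getitem__(self, name: str) -> Keypoint:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __iter__(self) -> Iterator[str]:
        return iter(n for n in LANDMARKS if n in self.points)

    def get(self, name: str) -> Optional[Keypoint]:
        return self.points.get(name)

    def visible(self, name: str) -> bool:
        """True when the landmark is present with visibility > 0."""
        kp = self.points.get(name)
        return kp is not None and kp.visibility > 0

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_dict(cls, raw: dict) -> "KeypointSet":
        kps = raw.get("keypoints")
        if kps is None:
            raise ValidationError("keypoint record has no 'keypoints' field")
        points: Dict[str, Keypoint] = {}
        if isinstance(kps, dict):
            for name, triple in kps.items():
                points[name] = Keypoint(float(triple[0]), float(triple[1]),
                                        int(triple[2]) if len(triple) > 2 else 2)
        elif isinstance(kps, (list, tuple)):
            flat = list(kps)
            # accept either nested triples or a fully flat COCO list
            if flat and not isinstance(flat[0], (list, tuple)):
                if len(flat) != 3 * len(LANDMARKS):
                    raise ValidationError(
                        f"flat keypoint list must have {3 * len(LANDMARKS)} "
                        f"entries, got {len(flat)}")
                flat = [flat[i:i + 3] for i in range(0, len(flat), 3)]
            if len(flat) != len(LANDMARKS):
                raise ValidationError(
                    f"expected {len(LANDMARKS)} keypoint triples, got {len(flat)}")
            for name, triple in zip(LANDMARKS, flat):
                points[name] = Keypoint(float(triple[0]), float(triple[1]),
                                        int(triple[2]))
        else:
            raise ValidationError(f"unsupported keypoints layout: {type(kps)}")
        return cls(points=points, image=raw.get("image"), bbox=raw.get("bbox"))

    @classmethod
    def from_json(cls, path: str | Path) -> "KeypointSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        out: dict = {
            "keypoints": {name: [kp.u, kp.v, kp.visibility]
                          for name, kp in self.points.items()},
        }
        if self.image is not None:
            out["image"] = self.image
        if self.bbox is not None:
            out["bbox"] = list(self.bbox)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
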