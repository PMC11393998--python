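"""File-level plumbing: scene directories, measurement tables, configs.

A simulated scene directory holds, per animal ``i``::

    depth_000i.png      16-bit grayscale, 1 sample = 1 mm
    keypoints_000i.json name-keyed landmark record with bbox
    truth.csv           analytic dimensions, one row per animal
    scene.yaml          model, pose and noise parameters + seed

which is exactly the input contract of the measurement pipeline, so
``simulate`` output feeds ``measure`` directly.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .camera import CameraIntrinsics
from .depth import save_depth_image
from .measure import MEASUREMENT_NAMES, MeasurementResult
from .synthetic import (
    DEFAULT_INTRINSICS,
    CameraPose,
    CattleModel,
    NoiseSpec,
    ground_truth_keypoints,
    inject_depth_noise,
    random_model,
    render_depth,
    true_dimensions,
)

__all__ = ["write_scenes", "measurements_to_csv", "read_measurement_csv"]


def _model_params(m: CattleModel) -> dict:
    d = asdict(m)
    d.pop("anchors", None)
    return d


def write_scenes(
    out_dir: str | Path,
    n: int,
    seed: int,
    K: CameraIntrinsics = DEFAULT_INTRINSICS,
    pose: CameraPose = CameraPose(),
    noise: NoiseSpec = NoiseSpec(),
    models: Optional[Sequence[CattleModel]] = None,
) -> pd.DataFrame:
    """Generate ``n`` scenes into ``out_dir``; returns the truth table.

    Models are drawn from :func:`bovimetry.synthetic.random_model` seeded
    by ``seed`` unless given explicitly; noise seeds derive from ``seed``
    per scene, so a (seed, n) pair regenerates the directory bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    manifest: List[dict] = []
    for i in range(n):
        model = models[i] if models is not None else random_model(rng)
        img = render_depth(model, pose, K)
        kps = ground_truth_keypoints(model, pose, K, img=img)
        scene_noise = NoiseSpec(
            dropout_rate=noise.dropout_rate, jitter_sd=noise.jitter_sd,
            hole_count=noise.hole_count, hole_radius=noise.hole_radius,
            seed=seed + 1 + i)
        noisy = inject_depth_noise(img, scene_noise)
        depth_name = f"depth_{i:04d}.png"
        kp_name = f"keypoints_{i:04d}.json"
        save_depth_image(noisy, out / depth_name)
        kps.image = depth_name
        kps.to_json(out / kp_name)
        truth = true_dimensions(model)
        rows.append({"id": i, **{k: round(v, 4) for k, v in truth.as_row().items()}})
        manifest.append({
            "id": i, "depth": depth_name, "keypoints": kp_name,
            "model": {k: float(v) for k, v in _model_params(model).items()},
            "noise_seed": scene_noise.seed,
        })
    truth_df = pd.DataFrame(
        rows, columns=["id", *MEASUREMENT_NAMES]).astype({"id": int})
    truth_df.to_csv(out / "truth.csv", index=False)
    with open(out / "scene.yaml", "w") as fh:
        yaml.safe_dump({
            "seed": seed,
            "n": n,
            "intrinsics": K.to_dict(),
            "pose": {"distance": pose.distance, "height": pose.height,
                     "lateral": pose.lateral},
            "noise": {"dropout_rate": noise.dropout_rate,
                      "jitter_sd": noise.jitter_sd,
                      "hole_count": noise.hole_count,
                      "hole_radius": noise.hole_radius},
            "scenes": manifest,
        }, fh, sort_keys=True)
    return truth_df


def measurements_to_csv(
    results: Dict[object, MeasurementResult], path: str | Path
) -> pd.DataFrame:
    """Write one row per animal; absent dimensions stay empty cells."""
    rows = []
    for rid, res in results.items():
        row: dict = {"id": rid}
        for name in MEASUREMENT_NAMES:
            val = getattr(res, name)
            row[name] = "" if val is None else f"{val:.1f}"
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", *MEASUREMENT_NAMES])
    df.to_csv(path, index=False)
    return df


def read_measurement_csv(path: str | Path) -> pd.DataFrame:
    """Read a measurement or truth CSV indexed by animal id."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: measurement CSV needs an 'id' column")
    return df.set_index("id")
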