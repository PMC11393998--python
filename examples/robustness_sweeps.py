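"""Distance and depth-noise robustness of the measurements.

Re-measures the same animal from several camera distances, then under
increasing depth jitter, mirroring how a field rig's accuracy depends on
standoff distance and sensor quality.
"""

import numpy as np

import bovimetry as bv

model = bv.build_cattle_model()
K = bv.DEFAULT_INTRINSICS
truth = bv.true_dimensions(model)
DIMS = ("body_height_cm", "lumbar_height_cm", "body_length_cm", "chest_girth_cm")

print("camera distance sweep (noiseless):")
print(f"{'flank dist':>10} " + "".join(f"{d.replace('_cm',''):>16}" for d in DIMS))
for dist in (2450.0, 3000.0, 3500.0, 4000.0):
    pose = bv.CameraPose(distance=dist)
    img = bv.render_depth(model, pose, K)
    kps = bv.ground_truth_keypoints(model, pose, K, img=img)
    res = bv.measure_animal(img, kps, K)
    flank = (dist - model.torso_semi_depth) / 1000.0
    print(f"{flank:>9.2f}m " + "".join(f"{getattr(res, d):>15.1f} " for d in DIMS))
print("-> height / lumbar / length are metric: they barely move with distance."
      "\n-> girth shifts a few percent: the visible flank arc and its pixel"
      "\n   sampling change with standoff distance.\n")

print("depth jitter sweep (MAE vs truth, cm, 3 replicates):")
pose = bv.CameraPose()
img = bv.render_depth(model, pose, K)
kps = bv.ground_truth_keypoints(model, pose, K, img=img)
for sd in (0.0, 5.0, 15.0, 30.0):
    errs = {d: [] for d in DIMS}
    for rep in range(3):
        noisy = (bv.inject_depth_noise(img, bv.NoiseSpec(jitter_sd=sd, seed=rep))
                 if sd > 0 else img)
        res = bv.measure_animal(noisy, kps, K)
        for d in DIMS:
            errs[d].append(abs(getattr(res, d) - getattr(truth, d)))
    print(f"  jitter {sd:4.0f} mm: " +
          " ".join(f"{d.replace('_cm','')}={np.mean(errs[d]):5.2f}" for d in DIMS))
print("-> errors of the three landmark distances grow with sensor noise; the"
      "\n   girth's large visibility bias dominates its error at every level.")
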