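"""Render a synthetic cow and measure it end to end.

Builds the default parametric animal (withers ~1.25 m, torso 1.5 m, chest
section 900 x 700 mm), renders its depth map from a tripod-height camera
3 m away, projects the seven landmark anchors into the image, and runs the
full measurement pipeline on the result.
"""

import bovimetry as bv

model = bv.build_cattle_model()
pose = bv.CameraPose()              # 3 m from the centre plane, 1 m high
K = bv.DEFAULT_INTRINSICS

img = bv.render_depth(model, pose, K)
kps = bv.ground_truth_keypoints(model, pose, K, img=img)
result = bv.measure_animal(img, kps, K)
truth = bv.true_dimensions(model)

print(f"reference depth (flank): {result.reference_depth_mm:.0f} mm")
print(f"{'dimension':<18}{'measured':>10}{'true':>10}{'error':>9}")
for dim in ("body_height_cm", "lumbar_height_cm",
            "body_length_cm", "chest_girth_cm"):
    got, want = getattr(result, dim), getattr(truth, dim)
    print(f"{dim:<18}{got:>9.1f} {want:>9.1f} {100 * (got - want) / want:>+8.2f}%")

# Height, length and lumbar height come back within a fraction of a percent:
# those landmarks are directly visible and the pinhole inversion is exact on
# rendered depths.  The girth is systematically low: a single side view only
# sees the near flank between the two silhouette tangencies, and mirroring
# that arc reconstructs twice the visible arc, not the full perimeter.
arc2 = 2 * bv.chest_anchor_arc(model) / 10.0
print(f"\nvisible-arc oracle (2 x flank arc): {arc2:.1f} cm "
      f"(girth deviates {100 * (result.chest_girth_cm - arc2) / arc2:+.2f}% from it)")
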