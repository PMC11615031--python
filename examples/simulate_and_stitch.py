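"""Two-lane acquisition, reconstruction, self-calibration and stitching.

Builds a normal colorectal-wall phantom, scans it in two parallel lanes
(0.3 mm apart, 10 stops of 0.1 mm), reconstructs the sector B-scans, then
pretends the sector angle is mis-recorded by +3 degrees and recovers the
true 20 degrees from the overlap of adjacent lanes before compositing a
stitched cross-section.  Takes about a minute on one CPU.
"""

import numpy as np

import coloct
from coloct.reconstruct import process_dataset

phantom = coloct.make_normal_wall_phantom(extent_mm=(3.0, 2.0, 2.3),
                                          vessel_count=3, seed=7)
intr = coloct.scan_intrinsics()          # true field of view: 20 degrees
plan = coloct.ScanPlan(n_lanes=2, steps_per_lane=10, step_size=0.1,
                       lane_spacing=0.3)
dataset = coloct.simulate_scan(phantom, plan, intr, seed=1,
                               scatterer_density=5.0)
processed = process_dataset(dataset)

refined, trace = coloct.tune_intrinsics(
    processed, intr.with_(fov_angle=23.0), ("fov_angle",),
    bounds={"fov_angle": (19.0, 27.0)})
print(f"field of view initialised at 23.0 deg, "
      f"recovered {refined.fov_angle:.2f} deg after {len(trace)} "
      f"objective evaluations")

slice5 = coloct.build_slice(processed, 5, refined, pixel_size=0.005)
enhanced = coloct.enhance_contrast(slice5)
valid = enhanced.image.valid_mask
lanes = sorted(int(v) for v in set(enhanced.provenance[valid]))
print(f"stitched slice at x = {slice5.x_position:.1f} mm: "
      f"{valid.sum()} valid pixels from lanes {lanes}")
print(f"normalization window: p_low={enhanced.normalization['p_low']:.4g}, "
      f"p_high={enhanced.normalization['p_high']:.4g}, gamma="
      f"{enhanced.normalization['gamma']}")
# The recovered angle should sit within ~0.5 deg of 20; each stitched pixel
# comes from exactly one lane (nearest-apex rule, no averaging).
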