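"""Quantitative lesion features on a simulated polyp.

Generates an effaced, hyperreflective polyp phantom, scans one lane, and
runs the feature extractors: surface detection, LP/MM-band segmentation,
hyperreflectivity ratio, effacement, surface irregularity, imaging depth
and the attenuation coefficient.  Takes ~30 s on one CPU.
"""

import coloct
from coloct.features import FeatureConfig, analyze_sample
from coloct.reconstruct import process_dataset

phantom = coloct.make_polyp_phantom(extent_mm=(2.0, 2.0, 3.1),
                                    mucosal_thickness=0.6, effaced=True,
                                    epithelial_backscatter_gain=3.0,
                                    seed=3, submucosa_thickness=1.2)
intr = coloct.scan_intrinsics(samples_per_ascan=1408, working_distance=1.2)
plan = coloct.ScanPlan(n_lanes=1, steps_per_lane=3, step_size=0.1)
dataset = coloct.simulate_scan(phantom, plan, intr, seed=4,
                               noise_snr_db=25, scatterer_density=5.0)
processed = process_dataset(dataset)
images = [coloct.scan_convert(processed.bscans[(0, i)], intr, 0.005)
          for i in range(3)]
report = analyze_sample(images, FeatureConfig(attenuation_compensation=True))

print("ground truth flags:", phantom.lesion_flags)
print(f"hyperreflectivity: {report.hyperreflectivity_ratio:+.2f} dB "
      f"-> {'hyperreflective' if report.hyperreflective else 'not hyperreflective'}")
print(f"LP/MM band found in {report.band_fraction:.0%} of columns "
      f"-> {'effaced' if report.effacement else 'layered'}")
print(f"irregular surface in {report.irregular_fraction:.0%} of images "
      f"-> {'irregular' if report.irregular else 'smooth'}")
print(f"imaging depth: {report.imaging_depth:.2f} mm")
for region, fit in report.attenuation.items():
    print(f"attenuation ({region}): {fit['mu_per_mm']:.2f} /mm "
          f"(R^2 {fit['r_squared']:.2f})")
# The flags should match the ground truth: the epithelium reads several dB
# brighter than the submucosa, no bright band interrupts the mucosa, the
# surface is smooth, and useful signal ends about 1 mm below the surface.
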