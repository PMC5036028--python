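"""Segment the up and down boundaries of a defect stripe and measure the
error against ground truth.

A noiseless defect phantom runs through the full preprocessing chain
(denoise, surface fit, flatten, median smooth, crop, half-size
downscale, power law) and the two graph searches. The printed mean
absolute errors are in half-resolution pixels: values below 1 mean the
minimum-weight paths track the true stripe edges to sub-pixel accuracy.
"""

import numpy as np

from pearloct import PhantomSpec, generate_phantom, run_pipeline, sinusoid_profile

width = 1024
spec = PhantomSpec(
    has_defect=True,
    defect_top_profile=sinusoid_profile(width, depth=120, amplitude=20, tilt=0.02),
    defect_thickness_profile=np.full(width, 40.0),
    speckle_level=0.0,
    background_noise_sigma=0.0,
    seed=1,
)
img, truth = generate_phantom(spec)
res = run_pipeline(img)

up_truth = res.geometry.truth_to_segmented(truth.defect_up)
down_truth = res.geometry.truth_to_segmented(truth.defect_down)
print(f"up boundary   MAE {np.abs(res.up.rows - up_truth).mean():.3f} px, "
      f"path cost {res.up.path_cost:.3f}")
print(f"down boundary MAE {np.abs(res.down.rows - down_truth).mean():.3f} px, "
      f"path cost {res.down.path_cost:.3f}")
print(f"mean boundary gradients: up {res.grade.up_mean:+.1f}, down {res.grade.down_mean:+.1f} "
      "(gray levels per pixel; positive = dark-to-light)")
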