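"""NPC ring quantification on a synthetic field of nuclear pores.

Each 8-fold-symmetric ring is quantified for radius (radial-profile
model fit), visible corners (8-sector counting, alpha=0.93,
threshold=0.6) and adjacent-corner distances (two-peak line-profile
fits).  Ground truth: cryo-EM ring radius 53.5 nm, corner spacing
2*R*sin(pi/8) ~ 40.9 nm; labeling probability 0.85 per corner.
"""

import numpy as np

from exmqc import (
    NoiseModel,
    PhantomSpec,
    analyze_ring,
    npc_population_report,
    render_npc_field,
)

spec = PhantomSpec(
    pixel_size_nm=2.0, shape=(128, 128), psf_sigma_nm=12.0,
    noise=NoiseModel("poisson", peak_counts=300), seed=0,
)

rings = []
for seed in range(20):
    stack, _ = render_npc_field(
        PhantomSpec(2.0, (128, 128), 12.0, spec.noise, seed=seed),
        n_npcs=1, radius_nm=53.5, corner_prob=0.85,
    )
    try:
        rings.append(analyze_ring(stack.voxels, pixel_size_nm=2.0,
                                  psf_sigma_nm=12.0))
    except ValueError:
        continue  # too few labeled corners to form a ring

report = npc_population_report(rings, min_corners_for_radius=4)
print(f"rings analyzed      : {report['n_rings']}")
print(f"radius (>=4 corners): {report['radius_mean_nm']:.1f} +/- "
      f"{report['radius_sd_nm']:.1f} nm, median {report['radius_median_nm']:.1f} "
      "(truth 53.5)")
print(f"corner histogram 0-8: {report['corner_histogram']}")
print(f"adjacent distance   : {report['distance_mean_nm']:.1f} +/- "
      f"{report['distance_sd_nm']:.1f} nm over {report['n_distances']} pairs "
      f"(truth {2 * 53.5 * np.sin(np.pi / 8):.1f})")
print("Radius spread across rings is an upper bound on the expansion "
      "error at the ~50 nm scale.")
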