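"""Estimate a linear expansion factor from pre/post landmark distances.

Every pair of landmarks contributes the ratio of its post- to
pre-expansion separation; the mean over pairs is the expansion factor
used to convert physical distances into biological units.
"""

import numpy as np

from exmqc import LandmarkPairSet, expansion_factor_from_landmarks

# four landmarks in a specimen, physical nm, measured before and after
# expansion (a rigid rotation+shift of the expanded specimen is fine)
rng = np.random.default_rng(0)
pre = rng.uniform(0, 50_000, (4, 2))
theta = 0.35
rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
post = (pre * 20.8) @ rot.T + np.array([2e5, -1e5])
# ~1% measurement noise on the post coordinates
post += rng.normal(0, 300.0, post.shape)

factor, sd, ratios = expansion_factor_from_landmarks(LandmarkPairSet(pre, post))
print(f"per-pair ratios : {np.round(ratios, 2)}")
print(f"expansion factor: {factor:.2f} +/- {sd:.2f} (true 20.8)")
print("A 100 nm biological distance therefore spans "
      f"{100 * factor / 1000:.1f} um in the expanded gel.")
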