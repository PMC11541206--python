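"""Expansion-distortion analysis: recover a known warp and measure the
r.m.s. measurement error as a function of measurement length.

A pre-expansion image and a synthetically warped copy (smooth random
field, RMS 10 nm) stand in for pre-/post-expansion acquisitions of the
same field.  Rigid registration removes pose; B-spline nonrigid
registration recovers the residual deformation field, from which the
r.m.s. error of distance measurements is read per length.
"""

import numpy as np

from exmqc import (
    PhantomSpec,
    make_warp_pair,
    nonrigid_register,
    rms_error_curve,
)

spec = PhantomSpec(pixel_size_nm=4.0, shape=(192, 192), psf_sigma_nm=15.0, seed=11)
pre, post, truth = make_warp_pair(spec, amplitude_nm=10.0,
                                  correlation_length_nm=150.0)

field = nonrigid_register(pre, post, preprocess_sigma_px=2)
u_true = np.moveaxis(np.asarray(truth.parameters["displacement_nm"]), 0, -1)
m = field.valid_mask
rms_true = np.sqrt((u_true[m] ** 2).sum(1).mean())
corr = np.corrcoef(field.displacement_nm[m].ravel(), u_true[m].ravel())[0, 1]
print(f"deformation field: recovered RMS {field.rms_nm:.1f} nm "
      f"(truth {rms_true:.1f} nm), pointwise correlation {corr:.2f}")

curve = rms_error_curve(field, [100.0, 200.0, 400.0, 600.0], n_samples=500, seed=0)
for L, r, s in zip(curve.lengths_nm, curve.rms_nm, curve.sd_nm):
    print(f"  measurement length {L:6.0f} nm -> r.m.s. error {r:4.1f} nm "
          f"(s.d. {s:.1f})")
print("Distances measured across this field are uncertain by the r.m.s. "
      "values above — the distortion cost of expansion at each scale.")
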