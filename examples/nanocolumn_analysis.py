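"""Synaptic nanocolumn analysis on a two-channel synapse phantom.

The reference channel plays a presynaptic scaffold (e.g. RIM1/2), the
measured channel its postsynaptic partner (e.g. PSD95).  The 3D
autocorrelation g_a(r) of each segmented cluster reveals internal
nanodomains; the cross-enrichment of one channel around the other's
intensity peak quantifies their trans-synaptic alignment.
"""

import numpy as np

from exmqc import (
    NoiseModel,
    PhantomSpec,
    autocorrelation_ga,
    cross_enrichment,
    nanodomain_size,
    render_synapse_pair,
    segment_synapses,
    snr,
)

spec = PhantomSpec(
    pixel_size_nm=8.0, shape=(72, 72, 72), psf_sigma_nm=15.0,
    noise=NoiseModel("gaussian", snr=30), seed=5,
)
stack, truth = render_synapse_pair(
    spec, n_synapses=1, nanodomain_size_nm=60.0, n_nanodomains=2,
    trans_offset_nm=0.0, cleft_nm=80.0,
)

ref = segment_synapses(stack, channel="reference", n_keep=1)[0]
meas = segment_synapses(stack, channel="measured", n_keep=1)[0]
print(f"segmented clusters: {ref.volume_voxels} / {meas.volume_voxels} voxels")

ga = autocorrelation_ga(ref, shell_nm=8.0, max_radius_nm=300.0)
print(f"g_a(0..24nm) = {np.round(ga.values[:3], 2)}  (1 = homogeneous)")

# sizing works best where the 7-sigma threshold isolates the dense core
# of the cluster, so re-render at the lower staining intensity regime
spec_size = PhantomSpec(
    pixel_size_nm=8.0, shape=(72, 72, 72), psf_sigma_nm=10.0,
    noise=NoiseModel("gaussian", snr=10), seed=5,
)
stack_size, _ = render_synapse_pair(
    spec_size, n_synapses=1, nanodomain_size_nm=60.0, n_nanodomains=2,
)
core = segment_synapses(stack_size, channel="reference", n_keep=1)[0]
size, defined = nanodomain_size(
    autocorrelation_ga(core, shell_nm=8.0, max_radius_nm=300.0)
)
print(f"nanodomain size: {size:.0f} nm (rendered 60 nm before PSF blur)"
      if defined else "nanodomain size: undefined (curve still decaying)")

enr = cross_enrichment(meas, ref, shell_nm=8.0, max_radius_nm=150.0)
v = enr.values[np.isfinite(enr.values)]
print(f"enrichment at reference peak: {v[0]:.2f} (>1 = aligned), "
      f"far field {v[-1]:.2f}")

background = np.ones(stack.spatial_shape, bool)
for roi in (ref, meas):
    sl = tuple(slice(o, o + s) for o, s in zip(roi.origin, roi.mask.shape))
    background[sl] = False
value = snr(stack, [ref], background, channel="reference")[0]
print(f"SNR (signal mean / background s.d.): {value:.1f}")
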