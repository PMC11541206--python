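"""Microtubule sidewall peak-to-peak distances on a synthetic population.

Antibody-decorated microtubules image as two parallel rails; the
transverse intensity profile (averaged along the microtubule over a
185 nm box) is fitted with a sum of two Gaussians, and the distance
between the fitted centers is the sidewall spacing.  Ground truth here
is 62.1 nm, the population mean reported for ~20x single-shot
expansion.
"""

from exmqc import (
    NoiseModel,
    PhantomSpec,
    boxes_from_truth,
    extract_profile,
    fit_double_gaussian,
    population_stats,
    render_microtubules,
)

spec = PhantomSpec(
    pixel_size_nm=5.0,          # biological sampling
    shape=(512, 512),
    psf_sigma_nm=15.0,          # ~300 nm optical sigma / 20x expansion
    noise=NoiseModel("gaussian", snr=10),
    seed=7,
)
stack, truth = render_microtubules(spec, n_segments=25, separation_nm=62.1)

fits = [
    fit_double_gaussian(extract_profile(stack, box))
    for box in boxes_from_truth(truth.parameters)
]
stats = population_stats(fits)
print(f"segments fitted : {stats.n} of 25")
print(f"sidewall spacing: {stats.mean_nm:.1f} +/- {stats.sd_nm:.1f} nm "
      "(mean +/- s.d.; truth 62.1 nm)")
print("The s.d. over segments bounds the nanoscale error the imaging "
      "pipeline adds to a 62 nm structure.")
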