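"""Block-wise Fourier ring correlation resolution of an image pair.

Two acquisitions of the same field with independent noise share signal
but not noise; the spatial frequency at which their ring-wise Fourier
correlation drops below 1/7 defines the effective resolution.
Evaluating it per block maps resolution locally; the mean over valid
blocks is the global resolution.
"""

from exmqc import (
    NoiseModel,
    PhantomSpec,
    blockwise_frc,
    frc_curve,
    frc_resolution,
    make_frc_pair,
    render_microtubules,
)

spec = PhantomSpec(pixel_size_nm=5.0, shape=(384, 384), psf_sigma_nm=15.0, seed=13)
clean, _ = render_microtubules(spec, n_segments=36, separation_nm=62.1)
image_a, image_b = make_frc_pair(clean, NoiseModel("gaussian", snr=8), seed=1)

res = frc_resolution(frc_curve(image_a, image_b), pixel_size_nm=5.0)
print(f"whole-image FRC resolution: {res:.1f} nm")

result = blockwise_frc(image_a, image_b, block_px=128, overlap=0.5)
print(f"block-wise map: {result.n_valid} valid blocks, "
      f"mean {result.global_mean_nm:.1f} nm, median {result.global_median_nm:.1f} nm")
print("With a 15 nm PSF sigma the band limit sits near 2.8*sigma = 42 nm; "
      "resolution cannot beat the optics, whatever the expansion factor.")
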