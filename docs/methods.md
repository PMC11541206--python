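# Methods

This note documents the models behind each `exmqc` analysis, the parameter
choices that matter, what the synthetic phantoms do and do not emulate, and
the numerical decisions a user extending the package should know about.

## Units and carriers

Every quantitative result is in *biological units*: physical distance divided
by the linear expansion factor.  `ImageStack` carries the voxel grid, the
per-axis physical pixel size (nm at the detector) and the expansion factor
(≥ 1); `bio_pixel_size_nm` is their ratio and the unit of every nm readout.
Coordinates are voxel-center, 0-based; OME-TIFF round-trips store
PhysicalSize metadata in nm, with a JSON sidecar for the expansion factor and
channel names (OME pixel metadata has no standard slot for either).

## Phantoms

The generators render emitters by evaluating the Gaussian PSF analytically on
the sampling grid rather than binning point masses and blurring, which avoids
quantization bias at 2–5 nm pixels.  A point emitter of unit peak amplitude
therefore carries total intensity `2πσ²/px²` exactly (tested to 1e-6), and a
finite line source is a transverse Gaussian times an erf window in closed
form.

* **PSF.** Isotropic Gaussian, default σ = 15 nm biological — a ~300 nm
  optical σ imaged through ~20× expansion.  No vectorial or depth-dependent
  optics.
* **Noise.** `gaussian(snr)` adds white noise with s.d. = peak/snr;
  `poisson(peak_counts)` scales the clean image to a peak photon count and
  samples shot noise.  Default SNR 10 ≈ a conservative confocal acquisition;
  the synapse enrichment examples use SNR 30, the post-expansion-staining
  regime in which a 7σ segmentation threshold retains whole clusters (see
  below).
* **Microtubules** are two parallel line sources separated by the sidewall
  distance (default 62.1 nm, the population mean measured for
  antibody-decorated microtubules at ~20× expansion), placed on a tile grid
  with random orientations.  Real microtubules curve; segments here are
  straight, so profile averaging along the box is exact rather than
  approximate.
* **NPC rings** are eight identical point emitters equally spaced on a circle
  (default radius 53.5 nm, the cryo-EM reference), each present with a
  per-slot labeling probability, with a random global rotation per ring.
  NUP96 stoichiometry variation, double-ring 3D structure and linkage error
  are not modeled.
* **Synapses** are soft-edged spherical clusters per channel separated by a
  cleft (default 80 nm) along a random axis; nanodomains are Gaussian
  hotspots (FWHM default 60 nm) whose measured-channel copies are carried
  across the cleft and displaced laterally by the trans-synaptic offset.
  Real synapses are disc-like and their nanodomain count/brightness varies;
  the phantom's value is a *known* hotspot geometry, not realism.
* **Warp pairs** resample a random spot texture through Gaussian-filtered
  white-noise displacement fields scaled to an exact RMS amplitude; the
  stored truth field uses the convention `warped(x) = reference(x + u(x))`,
  the same convention the registration stage reports.
* **Determinism.** One seed per phantom call, split into per-structure
  sub-streams (`SeedSequence.spawn`), so output is bit-identical for a fixed
  spec and stable under appending structures.

## Expansion factor and preprocessing

The landmark estimator uses every unordered pair of matched landmarks:
`factor = mean(post_distance/pre_distance)`, ± sample s.d. — rigid-motion
invariant by construction.  Preprocessing follows the standard chain:
rolling-ball background subtraction (default radius 50 px; implemented via
`skimage.restoration.rolling_ball`, tolerance-compatible with but not
bit-identical to the Fiji plugin), optional Gaussian smoothing, optional
maximum z-projection, in that order, clamped at zero.

## Microtubule sidewall profiles

The transverse profile is sampled by bilinear interpolation on a rotated
grid: the box's long axis lies perpendicular to the microtubule (the profile
direction) and its short axis (default 185 nm) runs along the microtubule and
is averaged.  The fit model is `a₁G(x;μ₁,σ₁) + a₂G(x;μ₂,σ₂) + b` with
centers initialized at the two highest local maxima of a lightly smoothed
profile, σ initialized at 10 nm and bounded in [2 nm, length/2], and
amplitude/baseline bounds scaled to the data range so the fit is invariant
to affine intensity changes.  A fit whose centers collapse within one sample
spacing, or that fails to converge, is flagged rather than raised.
Population statistics use converged fits only.

## FRC

Each plane is Hann-apodized (blocks are not periodic; without apodization
edge leakage inflates high-frequency correlation), FFT'd, and correlated
over rings of one pixel-frequency width.  Resolution is `1/q*` where `q*` is
the first downward crossing of the threshold — fixed at 1/7, the standard
FRC convention — after a 3-ring moving average (the raw curve is kept).
Block-wise analysis uses 128 px blocks with 50 % overlap by default; blocks
whose curve never crosses are invalid, and if *no* block crosses (identical
or noise-free inputs) the global value is pinned at the Nyquist floor (2 px)
with an explicit warning.  Both mean and median over valid blocks are
reported, since either may serve as the global summary.

## Distortion

The rigid stage fits a similarity transform (translation, rotation,
isotropic scale — the recovered scale doubles as a residual expansion-factor
estimate) by multiresolution correlation optimization in SimpleITK;
registration below a correlation floor raises rather than silently returning
a bad pose.  The nonrigid stage presmooths both images (default σ = 4 px),
z-scores them, and fits a B-spline free-form deformation with L-BFGS-B on
the mean-squared metric — after z-scoring this has the same optimum as
correlation, which matters because ITK's correlation metric does not support
B-spline transforms.  Smoothness is regularized by the control-point spacing
(default 16 px, single stage; a spacing schedule runs coarse-to-fine with
field composition) rather than an explicit bending-energy term.  The
returned field maps aligned-post pixels to their pre-image positions in nm;
a border frame where the spline extrapolates is excluded from the valid
mask.

The r.m.s. curve samples, per measurement length L, point pairs `(p, q)`
with `|p−q| = L` uniformly in position and orientation inside the valid
mask, and evaluates `|(q+u(q)) − (p+u(p))| − L`; the r.m.s. over pairs (with
s.d. and pair count) is reported per length.  The statistic is invariant to
global field translation and zero for any isometric residual.  On phantom
warp pairs (RMS 10 nm, correlation length 150 nm) the pipeline recovers the
field RMS within ~10 % with pointwise correlation ≈ 0.97, and undistorted
noisy pairs yield sub-pixel r.m.s. curves at every length.

## Nanocolumn statistics

Segmentation thresholds at `background mean + 7 × background s.d.`;
background statistics come from a user mask, or, automatically, from the
volume's median/MAD (signal voxels are sparse, so both are
background-dominated; MAD avoids the variance underestimate a naive
"below-median voxels" rule produces).  Components are 26-connected; cluster
peaks are argmax after a 3-voxel median filter so single-voxel spikes cannot
define a peak.  Cross-channel pairing is mutual-nearest-centroid within
500 nm, standing in for manual identification of juxtaposed clusters.

`g_a(r)` divides the shell-binned sum of intensity products over ordered
voxel pairs by the same computation on a uniform object of identical shape
and mean intensity, so support geometry cancels exactly: a uniform cluster
gives `g_a ≡ 1` at machine precision.  The production path is
FFT-accelerated (zero-padded, with explicit pair-count normalization) and
agrees with an exhaustive pair-enumeration oracle to < 1e-6 on small ROIs;
distances honour anisotropic voxel sizes, and shell bins default to 5 nm
(no bin width is standard; 5 nm resolves the 40–80 nm domain scale without
starving shells of pairs).

The nanodomain size is the first radius past the curve's peak where the
smoothed derivative of `g_a` exceeds −0.001 /nm over a 3-bin window — the
decay has stopped.  "Flattening" has no canonical numeric definition; this
threshold was validated on synapse phantoms, where it tracks the
PSF-broadened hotspot FWHM (e.g. ≈ 52 nm for a rendered 60 nm domain), and
an alternative half-decay readout (`method="half_decay"`) is provided.  The
readout degrades when the decay slope is comparable to the tolerance
(large, low-contrast clusters) — it is a semi-quantitative size estimate by
nature.

Enrichment averages the measured cluster's intensity in shells around the
reference cluster's peak and divides by the cluster mean (the uniform
surrogate evaluated on the same shells).  By default the reference peak is
first translated by the vector between the two clusters' centroids — the
"shifted reference cluster" of the standard nanocolumn analysis — so that a
perfectly aligned trans-synaptic pair peaks at r = 0; without the shift the
curve would peak at the cleft distance instead.  `align="none"` disables
the shift.  SNR is the mean ROI intensity over the background s.d., on
background-subtracted input, with an explicit error if the background mask
touches an ROI.

## NPC quantification

The ring center comes from a weighted algebraic (Kåsa) circle fit to the
bright pixels: unlike the intensity centroid it stays unbiased when corners
are missing (a 7-corner ring biases the centroid by ~R/7 toward the
occupied side).  The radius readout fits the exact blurred-ring model
`A·i0e(rR/σ²)·exp(−(r−R)²/2σ²) + b` to the azimuthally averaged profile:
the profile's raw peak sits `≈ σ²/2R` *inside* the true radius (≈ 2 nm at
R = 53.5, σ = 15), so the naive peak readout — retained as
`method="peak"` — is biased low by that amount while the model fit is not.

Corner counting splits the annulus `[0.93·R, R/0.93]` (α as printed for the
counting-corners scheme; only ±1 px of discretization padding, since a wider
annulus lets sector boundaries approach neighbouring corners and inflates
empty-sector signal) into eight 45° sectors phased on the ring's eightfold
symmetry: the phase of the 8th circular harmonic of the annulus intensity,
weighted quadratically to emphasize corner cores.  This makes the partition
rotation-equivariant — counts are invariant under arbitrary patch rotation.
A sector counts when its maximum, normalized to the brightest sector's
maximum, reaches the threshold (0.6).  Adjacent-corner distances sample a
thin line profile along the chord between neighbouring detected corners
(extended 1.5 PSF σ past each corner — a longer window would pick up the
next corners' tails) and reuse the double-Gaussian fit; population reports
apply the standard selection rule that only rings with ≥ 4 visible corners
enter radius statistics, while every ring enters the corner histogram.

## Recovery benchmarks and problem sizes

`scripts/acceptance.py` (and the mirror tests) re-derive three quantities
from scratch: NPC ring radius at the 53.5 nm cryo-EM reference, mean over 50
Poisson-noise seeds (pixel 2 nm, σ_PSF 15 nm, peak 200 counts);
adjacent-corner spacing at the 42 nm cryo-EM reference over 100 rings
(σ_PSF 12 nm, Gaussian SNR 10; the spacing fixes the radius through
`2R·sin(π/8)`); and the microtubule sidewall mean over 100 segments at
62.1 nm (pixel 5 nm, σ_PSF 15 nm, SNR 10).  These sizes give sub-0.5 nm
standard errors on each mean while keeping the full run around half a
minute on one CPU.  Typical recovered means: 53.50 nm, 41.9 nm, 62.1 nm.

## What passing phantoms does and does not show

Phantom recovery demonstrates that the estimators are unbiased and the
implementations correct under the stated image-formation model.  It does not
validate the model itself against a real microscope (non-Gaussian PSFs,
depth aberration, antibody linkage error, gel inhomogeneity), nor the manual
steps it automates (synapse/NPC selection, background outlining).  Real-data
population spreads (e.g. ±8.8 nm on sidewall distances) include biological
variability that phantoms deliberately lack.
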