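# exmqc — quantitative validation for high-expansion-factor expansion microscopy

Expansion microscopy (ExM) embeds a specimen in a swellable hydrogel and
physically magnifies it, so that nanoscale structure becomes resolvable on a
conventional confocal microscope.  Claims about an ExM protocol — its
expansion factor, its effective resolution, how little it distorts the
specimen — are quantitative claims, and `exmqc` packages the analyses used to
substantiate them for ~20× single-shot protocols:

* **expansion factor** from matched pre-/post-expansion landmark distances
  (mean ± s.d. of per-pair ratios);
* **resolution** by block-wise Fourier ring correlation (FRC): for two
  acquisitions of the same field with independent noise,
  `FRC(q) = Re Σ_ring F_A·F̄_B / √(Σ|F_A|² Σ|F_B|²)`, with resolution `1/q*`
  at the first 1/7-threshold crossing, mapped per block and summarized as the
  mean/median over valid blocks;
* **distortion** as the r.m.s. measurement error vs measurement length,
  computed from the deformation vector field that a similarity + B-spline
  free-form registration recovers between pre- and post-expansion images;
* **microtubule sidewall spacing**: box-averaged transverse profiles fitted
  with a sum of two Gaussians; the peak-to-peak distance over a population of
  segments benchmarks nanoscale accuracy (expected ≈ 62 nm for
  antibody-decorated microtubules);
* **synaptic nanocolumns**: 3D autocorrelation `g_a(r)` of segmented synaptic
  clusters (normalized by a uniform object of identical shape, so `g_a ≡ 1`
  for a homogeneous cluster), nanodomain size from where `g_a` flattens,
  cross-channel enrichment around the partner channel's intensity peak, and
  SNR;
* **NPC rings**: ring radius from the azimuthally averaged radial profile,
  per-ring corner counts by the 8-sector counting-corners scheme
  (α = 0.93, threshold = 0.6), and adjacent-corner distances by two-peak
  line-profile fits (cryo-EM references: radius 53.5 nm, spacing 42 nm).

All distances are reported in **biological units** — physical nanometres
divided by the linear expansion factor.

Because the analyses are meant to be verifiable without microscope data, the
`phantoms` module renders every structure with exact ground truth (paired
parallel-line microtubules, 8-fold NPC rings with per-corner labeling,
two-channel synaptic clusters with nanodomains and a controllable
trans-synaptic offset, smooth random warps, independent-noise FRC pairs); the
test suite is built on parameter recovery against those truths.

## Worked example

```python
from exmqc import (PhantomSpec, NoiseModel, render_microtubules,
                   boxes_from_truth, extract_profile, fit_double_gaussian,
                   population_stats)

spec = PhantomSpec(pixel_size_nm=5.0, shape=(512, 512), psf_sigma_nm=15.0,
                   noise=NoiseModel("gaussian", snr=10), seed=7)
stack, truth = render_microtubules(spec, n_segments=25, separation_nm=62.1)
fits = [fit_double_gaussian(extract_profile(stack, b))
        for b in boxes_from_truth(truth.parameters)]
stats = population_stats(fits)
print(f"{stats.mean_nm:.1f} +/- {stats.sd_nm:.1f} nm over {stats.n} segments")
```

prints

```
62.1 +/- 0.2 nm over 25 segments
```

i.e. the double-Gaussian pipeline recovers the rendered 62.1 nm sidewall
spacing without bias, and the 0.2 nm spread is the estimator noise at SNR 10
— any larger spread on real data reflects biology plus expansion error.  The
scripts in `examples/` walk through each capability the same way
(`python examples/frc_resolution.py`, `examples/npc_quantification.py`, ...)
and print what the numbers mean.

A thin CLI covers the file-oriented entry points:

```bash
exmqc phantom npc --n 9 --pixel-size 2 --seed 1 --out npc.ome.tiff
exmqc expansion-factor landmarks.csv --out factor.json
exmqc frc a.ome.tiff b.ome.tiff --block 128 --out frcmap
```

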