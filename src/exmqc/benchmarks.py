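"""Parameter-recovery benchmarks on reference geometries.

Each benchmark renders phantoms whose ground truth is a published
reference geometry — the cryo-EM NPC ring radius (53.5 nm), the cryo-EM
adjacent-corner spacing (42 nm), and the microtubule sidewall spacing
measured for antibody-decorated microtubules under ~20x expansion
(62.1 nm) — runs the corresponding estimator end to end, and reports
the population mean.  They double as regression checks that the
estimators are unbiased at realistic noise levels.
"""

from __future__ import annotations

import numpy as np

from . import mt_profile
from .npc import analyze_ring, radial_profile_radius
from .phantoms import (
    NPC_CORNER_SPACING_CRYOEM_NM,
    NPC_RADIUS_CRYOEM_NM,
    NoiseModel,
    PhantomSpec,
    render_microtubules,
    render_npc_field,
)

__all__ = [
    "MT_SIDEWALL_REFERENCE_NM",
    "npc_radius_recovery",
    "npc_corner_spacing_recovery",
    "mt_sidewall_recovery",
]

#: population-mean sidewall peak-to-peak distance of antibody-decorated
#: microtubules under ~20x single-shot expansion (biological nm)
MT_SIDEWALL_REFERENCE_NM = 62.1


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


def npc_radius_recovery(
    seed: int = 0,
    n_seeds: int = 50,
    radius_nm: float = NPC_RADIUS_CRYOEM_NM,
    psf_sigma_nm: float = 15.0,
    pixel_size_nm: float = 2.0,
    peak_counts: float = 200.0,
) -> dict:
    """Ring-radius estimation on Poisson-noise NPC phantoms.

    Renders one fully labeled 8-corner ring per noise seed at the
    cryo-EM reference radius and estimates each radius from the
    azimuthally averaged radial profile about the refined center.
    """
    radii = []
    for s in _subseeds(seed, n_seeds):
        spec = PhantomSpec(
            pixel_size_nm, (128, 128), psf_sigma_nm,
            noise=NoiseModel("poisson", peak_counts=peak_counts), seed=s,
        )
        stack, _ = render_npc_field(spec, 1, radius_nm=radius_nm)
        r, _, _ = radial_profile_radius(
            stack.voxels, pixel_size_nm=pixel_size_nm
        )
        radii.append(r)
    radii = np.array(radii)
    return {
        "mean_nm": float(radii.mean()),
        "sd_nm": float(radii.std(ddof=1)),
        "n": int(radii.size),
        "truth_nm": radius_nm,
    }


def npc_corner_spacing_recovery(
    seed: int = 0,
    n_npcs: int = 100,
    spacing_nm: float = NPC_CORNER_SPACING_CRYOEM_NM,
    psf_sigma_nm: float = 12.0,
    pixel_size_nm: float = 2.0,
    snr: float = 10.0,
) -> dict:
    """Adjacent-corner distances on fully labeled noisy NPC phantoms.

    Ground-truth spacing fixes the ring radius via the chord relation
    ``spacing = 2 R sin(pi/8)``; every adjacent pair found by the
    corner-counting step is measured by the two-peak line-profile fit.
    """
    radius_nm = spacing_nm / (2 * np.sin(np.pi / 8))
    distances: list[float] = []
    for s in _subseeds(seed, n_npcs):
        spec = PhantomSpec(
            pixel_size_nm, (128, 128), psf_sigma_nm,
            noise=NoiseModel("gaussian", snr=snr), seed=s,
        )
        stack, _ = render_npc_field(spec, 1, radius_nm=radius_nm)
        ring = analyze_ring(
            stack.voxels, pixel_size_nm=pixel_size_nm,
            psf_sigma_nm=psf_sigma_nm,
        )
        distances.extend(ring.adjacent_distances_nm)
    d = np.array(distances)
    return {
        "mean_nm": float(d.mean()),
        "sd_nm": float(d.std(ddof=1)),
        "n": int(d.size),
        "n_npcs": n_npcs,
        "truth_nm": spacing_nm,
    }


def mt_sidewall_recovery(
    seed: int = 0,
    n_segments: int = 100,
    separation_nm: float = MT_SIDEWALL_REFERENCE_NM,
    psf_sigma_nm: float = 15.0,
    pixel_size_nm: float = 5.0,
    snr: float = 10.0,
) -> dict:
    """Sidewall peak-to-peak distances over a microtubule population.

    100 randomly oriented straight segments at the ground-truth
    separation; box-averaged 185-nm transverse profiles fitted with a
    sum of two Gaussians; mean over converged fits.
    """
    spec = PhantomSpec(
        pixel_size_nm, (1024, 1024), psf_sigma_nm,
        noise=NoiseModel("gaussian", snr=snr), seed=seed,
    )
    stack, truth = render_microtubules(
        spec, n_segments, separation_nm, orientation_policy="random"
    )
    fits = [
        mt_profile.fit_double_gaussian(mt_profile.extract_profile(stack, box))
        for box in mt_profile.boxes_from_truth(truth.parameters)
    ]
    stats = mt_profile.population_stats(fits)
    return {
        "mean_nm": stats.mean_nm,
        "sd_nm": stats.sd_nm,
        "n": stats.n,
        "truth_nm": separation_nm,
    }
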