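"""Synthetic phantoms with known ground truth for every analysis stage.

Each generator renders the structure its analysis module quantifies —
paired parallel-line microtubules, eightfold-symmetric NPC rings with
per-corner labeling, two-channel synaptic clusters with nanodomains and
a controllable trans-synaptic offset, smooth random warps, and
independent-noise image pairs — and returns the exact geometry used to
render it, so every estimator has a parameter-recovery oracle.

Conventions
-----------
* All coordinates and lengths are nanometres in biological units; the
  grid sampling is ``PhantomSpec.pixel_size_nm``.
* Emitters are rendered by analytic evaluation of the Gaussian PSF on
  the grid (not binning-then-blurring), so a point emitter of unit peak
  amplitude carries total intensity ``2*pi*sigma^2 / px^2`` in 2D.
* A fixed ``(spec, seed)`` produces bit-identical output.  Per-structure
  randomness uses deterministically spawned sub-streams, so rendering
  n structures and then one more leaves the first n unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .core import ImageStack, write_stack

__all__ = [
    "NoiseModel",
    "PhantomSpec",
    "GroundTruth",
    "render_microtubules",
    "render_npc_field",
    "render_synapse_pair",
    "make_warp_pair",
    "make_frc_pair",
    "save_phantom",
    "NPC_RADIUS_CRYOEM_NM",
    "NPC_CORNER_SPACING_CRYOEM_NM",
]

#: Cryo-EM reference geometry of the nuclear pore complex (NUP96 ring):
#: ring radius and the chord between adjacent corners of the 8-fold ring.
NPC_RADIUS_CRYOEM_NM = 53.5
NPC_CORNER_SPACING_CRYOEM_NM = 42.0


@dataclass
class NoiseModel:
    """Detection-noise model applied after rendering.

    kind 'none'    — clean image.
    kind 'gaussian'— additive white noise with s.d. = peak signal / snr.
    kind 'poisson' — image scaled so its maximum equals ``peak_counts``,
                     then Poisson-sampled (shot-noise limit).
    """

    kind: str = "none"
    snr: float = 10.0
    peak_counts: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "gaussian" and self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.kind == "poisson" and self.peak_counts <= 0:
            raise ValueError("peak_counts must be > 0")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return image.copy()
        peak = float(image.max())
        if peak == 0:
            return image.copy()
        if self.kind == "gaussian":
            return image + rng.normal(0.0, peak / self.snr, image.shape)
        scaled = image * (self.peak_counts / peak)
        return rng.poisson(scaled).astype(float)


@dataclass
class PhantomSpec:
    """Sampling, optics and noise shared by all phantom generators.

    pixel_size_nm is the *biological* sampling (post-division by the
    expansion factor); psf_sigma_nm is the isotropic Gaussian PSF width
    in the same units (default 15 nm: a ~300 nm optical sigma imaged
    through ~20x expansion).
    """

    pixel_size_nm: float = 2.0
    shape: tuple[int, ...] = (256, 256)
    psf_sigma_nm: float = 15.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    expansion_factor: float = 20.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be >= 0")
        self.shape = tuple(int(s) for s in self.shape)

    @property
    def sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    def stack(self, voxels: np.ndarray, channel_names=None) -> ImageStack:
        """Wrap a rendered array, restoring physical pixel size."""
        nd = voxels.ndim - (1 if channel_names else 0)
        phys = self.pixel_size_nm * self.expansion_factor
        return ImageStack(voxels, (phys,) * nd, self.expansion_factor, channel_names)

    def streams(self, n: int) -> list[np.random.Generator]:
        """n+1 independent sub-streams: one per structure plus one for noise."""
        seqs = np.random.SeedSequence(self.seed).spawn(n + 1)
        return [np.random.default_rng(s) for s in seqs]


@dataclass
class GroundTruth:
    """Exact geometry used to render a phantom."""

    structure_kind: str
    parameters: dict

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(
            {"structure_kind": self.structure_kind, "parameters": self.parameters},
            default=_default,
            indent=1,
        )


def save_phantom(stack: ImageStack, truth: GroundTruth, path: str | Path) -> None:
    """Write the image as OME-TIFF and the ground truth as sidecar JSON."""
    path = Path(path)
    write_stack(stack, path)
    path.with_suffix(path.suffix + ".truth.json").write_text(truth.to_json())


# ---------------------------------------------------------------------------
# analytic emitters
# ---------------------------------------------------------------------------


def _add_gaussian_spot_2d(img, y0, x0, sigma, amplitude=1.0, cutoff=6.0):
    """Add a 2D Gaussian of unit peak amplitude at (y0, x0) (pixel coords)."""
    h, w = img.shape
    r = cutoff * sigma
    ylo, yhi = max(0, int(np.floor(y0 - r))), min(h, int(np.ceil(y0 + r)) + 1)
    xlo, xhi = max(0, int(np.floor(x0 - r))), min(w, int(np.ceil(x0 + r)) + 1)
    if ylo >= yhi or xlo >= xhi:
        return
    yy = np.arange(ylo, yhi)[:, None] - y0
    xx = np.arange(xlo, xhi)[None, :] - x0
    img[ylo:yhi, xlo:xhi] += amplitude * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def _add_gaussian_spot_3d(vol, z0, y0, x0, sigmas, amplitude=1.0, cutoff=5.0):
    sz, sy, sx = sigmas
    d, h, w = vol.shape
    zlo, zhi = max(0, int(z0 - cutoff * sz)), min(d, int(z0 + cutoff * sz) + 2)
    ylo, yhi = max(0, int(y0 - cutoff * sy)), min(h, int(y0 + cutoff * sy) + 2)
    xlo, xhi = max(0, int(x0 - cutoff * sx)), min(w, int(x0 + cutoff * sx) + 2)
    if zlo >= zhi or ylo >= yhi or xlo >= xhi:
        return
    zz = ((np.arange(zlo, zhi) - z0) / sz)[:, None, None]
    yy = ((np.arange(ylo, yhi) - y0) / sy)[None, :, None]
    xx = ((np.arange(xlo, xhi) - x0) / sx)[None, None, :]
    vol[zlo:zhi, ylo:yhi, xlo:xhi] += amplitude * np.exp(
        -(zz**2 + yy**2 + xx**2) / 2.0
    )


def _add_line_segment_2d(img, p0, p1, sigma, amplitude=1.0, cutoff=6.0):
    """Add a PSF-blurred line segment from p0 to p1 (pixel coords, (y, x)).

    A uniform line source convolved with a Gaussian is, in closed form, a
    transverse Gaussian times an erf window along the axis; unit
    amplitude means unit peak for a long segment.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = np.linalg.norm(p1 - p0)
    if length == 0:
        _add_gaussian_spot_2d(img, p0[0], p0[1], sigma, amplitude)
        return
    u = (p1 - p0) / length
    h, w = img.shape
    r = cutoff * sigma
    ylo = max(0, int(np.floor(min(p0[0], p1[0]) - r)))
    yhi = min(h, int(np.ceil(max(p0[0], p1[0]) + r)) + 1)
    xlo = max(0, int(np.floor(min(p0[1], p1[1]) - r)))
    xhi = min(w, int(np.ceil(max(p0[1], p1[1]) + r)) + 1)
    if ylo >= yhi or xlo >= xhi:
        return
    yy = np.arange(ylo, yhi)[:, None] - p0[0]
    xx = np.arange(xlo, xhi)[None, :] - p0[1]
    t = yy * u[0] + xx * u[1]  # along-axis coordinate
    d = -yy * u[1] + xx * u[0]  # transverse coordinate
    s2 = sigma * np.sqrt(2.0)
    axial = 0.5 * (erf(t / s2) - erf((t - length) / s2))
    img[ylo:yhi, xlo:xhi] += amplitude * np.exp(-(d**2) / (2 * sigma**2)) * axial


def _tile_centers(shape, n, rng=None, jitter_frac=0.0):
    """Centers of n near-square tiles covering a 2D shape (pixel coords)."""
    if n == 0:
        return np.empty((0, 2)), (shape[0], shape[1])
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    th, tw = shape[0] / rows, shape[1] / cols
    centers = []
    for i in range(n):
        r, c = divmod(i, cols)
        cy, cx = (r + 0.5) * th, (c + 0.5) * tw
        if rng is not None and jitter_frac > 0:
            cy += rng.uniform(-jitter_frac, jitter_frac) * th
            cx += rng.uniform(-jitter_frac, jitter_frac) * tw
        centers.append((cy, cx))
    return np.array(centers), (th, tw)


# ---------------------------------------------------------------------------
# microtubules: paired parallel line sources
# ---------------------------------------------------------------------------


def render_microtubules(
    spec: PhantomSpec,
    n_segments: int,
    separation_nm: float,
    orientation_policy: str = "random",
    segment_length_nm: float | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render straight microtubule segments as paired parallel lines.

    Each segment is two parallel line sources ``separation_nm`` apart
    (the antibody-decorated sidewalls), convolved with the PSF.  Truth
    records each segment's center, axis angle, length and separation.

    orientation_policy: 'random' (uniform angle per segment) or
    'horizontal' (axis along +x).
    """
    if separation_nm <= 2 * spec.pixel_size_nm:
        raise ValueError(
            f"separation {separation_nm} nm is below the Nyquist limit "
            f"for {spec.pixel_size_nm} nm pixels"
        )
    if orientation_policy not in ("random", "horizontal"):
        raise ValueError(f"unknown orientation_policy {orientation_policy!r}")

    img = np.zeros(spec.shape[-2:], dtype=float)
    *seg_rngs, noise_rng = spec.streams(n_segments)
    centers_px, (th, tw) = _tile_centers(img.shape, n_segments)
    px = spec.pixel_size_nm
    sep_px = separation_nm / px
    segments = []
    for i in range(n_segments):
        rng = seg_rngs[i]
        if orientation_policy == "random":
            angle = rng.uniform(0, 180.0)
        else:
            angle = 0.0
        if segment_length_nm is None:
            length_px = 0.7 * min(th, tw)
        else:
            length_px = segment_length_nm / px
        cy, cx = centers_px[i]
        a = np.deg2rad(angle)
        u = np.array([np.sin(a), np.cos(a)])  # (y, x) axis direction
        v = np.array([-u[1], u[0]])  # transverse
        for s in (-0.5, 0.5):
            off = s * sep_px * v
            p0 = np.array([cy, cx]) + off - 0.5 * length_px * u
            p1 = np.array([cy, cx]) + off + 0.5 * length_px * u
            _add_line_segment_2d(img, p0, p1, spec.sigma_px)
        segments.append(
            {
                "center_nm": [cy * px, cx * px],
                "angle_deg": angle,
                "length_nm": length_px * px,
                "separation_nm": separation_nm,
            }
        )
    noisy = spec.noise.apply(img, noise_rng)
    truth = GroundTruth(
        "microtubule",
        {"segments": segments, "psf_sigma_nm": spec.psf_sigma_nm,
         "pixel_size_nm": px, "clean_total_intensity": float(img.sum())},
    )
    return spec.stack(noisy), truth


# ---------------------------------------------------------------------------
# NPC rings: eight point emitters on a circle
# ---------------------------------------------------------------------------


def render_npc_field(
    spec: PhantomSpec,
    n_npcs: int,
    radius_nm: float = NPC_RADIUS_CRYOEM_NM,
    corner_prob: float | list[float] = 1.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a field of 8-fold-symmetric NPC rings.

    Corners are identical point emitters equally spaced on a circle of
    ``radius_nm``; slot k of each ring is labeled (present) with
    probability ``corner_prob[k]`` (scalar broadcast to all 8 slots).
    Each ring gets a random global rotation.  Truth records per-NPC
    center, rotation, present-corner mask and corner coordinates.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0")
    probs = np.broadcast_to(np.asarray(corner_prob, dtype=float), (8,))
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("corner probabilities must be in [0, 1]")

    img = np.zeros(spec.shape[-2:], dtype=float)
    *npc_rngs, noise_rng = spec.streams(n_npcs)
    centers_px, _ = _tile_centers(img.shape, n_npcs)
    px = spec.pixel_size_nm
    npcs = []
    for i in range(n_npcs):
        rng = npc_rngs[i]
        cy, cx = centers_px[i]
        # jitter keeps rings off the exact pixel lattice
        cy += rng.uniform(-1, 1)
        cx += rng.uniform(-1, 1)
        phase = rng.uniform(0, 45.0)
        present = rng.random(8) < probs
        corner_xy = []
        for k in range(8):
            ang = np.deg2rad(phase + 45.0 * k)
            y = cy + (radius_nm / px) * np.sin(ang)
            x = cx + (radius_nm / px) * np.cos(ang)
            corner_xy.append([y * px, x * px])
            if present[k]:
                _add_gaussian_spot_2d(img, y, x, spec.sigma_px)
        npcs.append(
            {
                "center_nm": [cy * px, cx * px],
                "radius_nm": radius_nm,
                "phase_deg": phase,
                "corners_present": present.tolist(),
                "corner_positions_nm": corner_xy,
            }
        )
    noisy = spec.noise.apply(img, noise_rng)
    truth = GroundTruth(
        "npc",
        {
            "npcs": npcs,
            "radius_nm": radius_nm,
            "corner_spacing_nm": 2 * radius_nm * np.sin(np.pi / 8),
            "psf_sigma_nm": spec.psf_sigma_nm,
            "pixel_size_nm": px,
            "n_emitters": int(sum(sum(n["corners_present"]) for n in npcs)),
            "clean_total_intensity": float(img.sum()),
        },
    )
    return spec.stack(noisy), truth


# ---------------------------------------------------------------------------
# two-channel synaptic clusters with nanodomains
# ---------------------------------------------------------------------------


def _soft_ball(vol, center, radius_px, edge_sigma_px, amplitude):
    """Uniform ball of given radius with an erf-smoothed (PSF-blurred) edge."""
    d, h, w = vol.shape
    r = radius_px + 5 * edge_sigma_px
    z0, y0, x0 = center
    zlo, zhi = max(0, int(z0 - r)), min(d, int(z0 + r) + 2)
    ylo, yhi = max(0, int(y0 - r)), min(h, int(y0 + r) + 2)
    xlo, xhi = max(0, int(x0 - r)), min(w, int(x0 + r) + 2)
    if zlo >= zhi or ylo >= yhi or xlo >= xhi:
        return
    zz = (np.arange(zlo, zhi) - z0)[:, None, None]
    yy = (np.arange(ylo, yhi) - y0)[None, :, None]
    xx = (np.arange(xlo, xhi) - x0)[None, None, :]
    dist = np.sqrt(zz**2 + yy**2 + xx**2)
    vol[zlo:zhi, ylo:yhi, xlo:xhi] += amplitude * 0.5 * (
        1 + erf((radius_px - dist) / (np.sqrt(2) * edge_sigma_px))
    )


def render_synapse_pair(
    spec: PhantomSpec,
    n_synapses: int,
    nanodomain_size_nm: float = 60.0,
    n_nanodomains: int = 3,
    trans_offset_nm: float = 0.0,
    cleft_nm: float = 80.0,
    cluster_radius_nm: float = 150.0,
    base_amplitude: float = 0.4,
) -> tuple[ImageStack, GroundTruth]:
    """Render juxtaposed two-channel synaptic clusters with nanodomains.

    Each synapse contributes one disc-like cluster per channel (soft
    balls of ``cluster_radius_nm``), separated by ``cleft_nm`` along a
    random axis.  Inside each cluster sit ``n_nanodomains`` Gaussian
    hotspots of FWHM ``nanodomain_size_nm``; measured-channel hotspots
    are the reference-channel hotspots carried across the cleft and
    displaced laterally by ``trans_offset_nm`` (the trans-synaptic
    alignment error).  Channels: 0 = reference, 1 = measured.
    """
    if nanodomain_size_nm <= 0:
        raise ValueError("nanodomain_size_nm must be > 0")
    if n_nanodomains > 0 and nanodomain_size_nm > 2 * cluster_radius_nm:
        raise ValueError("nanodomain larger than cluster")
    if len(spec.shape) != 3:
        raise ValueError("synapse phantoms require a 3D spec.shape")

    px = spec.pixel_size_nm
    vol_ref = np.zeros(spec.shape, dtype=float)
    vol_meas = np.zeros(spec.shape, dtype=float)
    *syn_rngs, noise_rng = spec.streams(n_synapses)

    # lay synapses out on a 3D grid of cells
    n_side = int(np.ceil(n_synapses ** (1 / 3)))
    cell = np.array(spec.shape) / n_side
    sig_psf = spec.sigma_px
    sig_nd = np.sqrt((nanodomain_size_nm / 2.3548) ** 2 + spec.psf_sigma_nm**2) / px

    synapses = []
    idx = 0
    for iz in range(n_side):
        for iy in range(n_side):
            for ix in range(n_side):
                if idx >= n_synapses:
                    break
                rng = syn_rngs[idx]
                c = (np.array([iz, iy, ix]) + 0.5) * cell
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                half = 0.5 * cleft_nm / px
                c_ref = c - half * axis
                c_meas = c + half * axis
                for vol, cc in ((vol_ref, c_ref), (vol_meas, c_meas)):
                    _soft_ball(vol, cc, cluster_radius_nm / px, sig_psf, base_amplitude)
                # lateral unit vector orthogonal to the cleft axis
                t = np.cross(axis, rng.normal(size=3))
                t /= np.linalg.norm(t)
                hot_ref, hot_meas = [], []
                for _ in range(n_nanodomains):
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    rad = 0.55 * cluster_radius_nm / px * rng.random() ** (1 / 3)
                    h_ref = c_ref + rad * d
                    h_meas = h_ref + (cleft_nm / px) * axis + (trans_offset_nm / px) * t
                    _add_gaussian_spot_3d(vol_ref, *h_ref, (sig_nd,) * 3)
                    _add_gaussian_spot_3d(vol_meas, *h_meas, (sig_nd,) * 3)
                    hot_ref.append((h_ref * px).tolist())
                    hot_meas.append((h_meas * px).tolist())
                synapses.append(
                    {
                        "center_nm": (c * px).tolist(),
                        "axis": axis.tolist(),
                        "hotspots_ref_nm": hot_ref,
                        "hotspots_meas_nm": hot_meas,
                    }
                )
                idx += 1
    noisy = np.stack(
        [spec.noise.apply(vol_ref, noise_rng), spec.noise.apply(vol_meas, noise_rng)]
    )
    truth = GroundTruth(
        "synapse",
        {
            "synapses": synapses,
            "nanodomain_size_nm": nanodomain_size_nm,
            "trans_offset_nm": trans_offset_nm,
            "cleft_nm": cleft_nm,
            "cluster_radius_nm": cluster_radius_nm,
            "pixel_size_nm": px,
        },
    )
    return spec.stack(noisy, channel_names=("reference", "measured")), truth


# ---------------------------------------------------------------------------
# warp pairs and FRC pairs
# ---------------------------------------------------------------------------


def _random_texture(spec: PhantomSpec, rng, n_spots=80) -> np.ndarray:
    """Random field of Gaussian spots: featureful content for registration."""
    img = np.zeros(spec.shape[-2:], dtype=float)
    h, w = img.shape
    margin = 4 * spec.sigma_px
    for _ in range(n_spots):
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        amp = rng.uniform(0.5, 1.0)
        _add_gaussian_spot_2d(img, y, x, spec.sigma_px * rng.uniform(1.0, 2.0), amp)
    return img


def make_warp_pair(
    spec: PhantomSpec,
    amplitude_nm: float,
    correlation_length_nm: float,
    n_spots: int = 80,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Reference image plus a smoothly warped copy, with the exact field.

    The displacement field is Gaussian-filtered white noise (correlation
    length -> filter sigma) scaled so the RMS displacement magnitude is
    ``amplitude_nm``.  The warped image samples the reference at
    ``x + u(x)``:  ``warped(x) = ref(x + u(x))`` (u in the stored truth,
    nm, ordered (uy, ux) per pixel).  amplitude 0 gives identical images.
    """
    if amplitude_nm < 0:
        raise ValueError("amplitude_nm must be >= 0")
    rng_tex, rng_field, _ = spec.streams(2)
    ref = _random_texture(spec, rng_tex, n_spots)
    h, w = ref.shape
    px = spec.pixel_size_nm
    if amplitude_nm == 0:
        u_nm = np.zeros((2, h, w))
        warped = ref.copy()
    else:
        sig = correlation_length_nm / px
        u = np.stack(
            [ndimage.gaussian_filter(rng_field.normal(size=(h, w)), sig)
             for _ in range(2)]
        )
        rms = np.sqrt(np.mean(np.sum(u**2, axis=0)))
        u *= (amplitude_nm / px) / rms
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        warped = ndimage.map_coordinates(
            ref, [yy + u[0], xx + u[1]], order=3, mode="nearest"
        )
        u_nm = u * px
    noise_rng_a, noise_rng_b = np.random.default_rng(
        np.random.SeedSequence(spec.seed).spawn(5)[3]
    ), np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(5)[4])
    truth = GroundTruth(
        "warp_pair",
        {
            "amplitude_nm": amplitude_nm,
            "correlation_length_nm": correlation_length_nm,
            "displacement_nm": u_nm,
            "pixel_size_nm": px,
        },
    )
    return (
        spec.stack(spec.noise.apply(ref, noise_rng_a)),
        spec.stack(spec.noise.apply(warped, noise_rng_b)),
        truth,
    )


def make_frc_pair(
    image: ImageStack, noise: NoiseModel, seed: int = 0
) -> tuple[ImageStack, ImageStack]:
    """Two acquisitions of the same clean image with independent noise."""
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    a = noise.apply(np.asarray(image.voxels, dtype=float), np.random.default_rng(s1))
    b = noise.apply(np.asarray(image.voxels, dtype=float), np.random.default_rng(s2))
    return image.with_voxels(a), image.with_voxels(b)
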