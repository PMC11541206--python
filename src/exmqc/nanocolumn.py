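"""Synaptic nanocolumn analysis: 3D segmentation, autocorrelation
g_a(r), cross-channel enrichment, nanodomain size and SNR.

A synapse imaged in two channels (presynaptic and postsynaptic scaffold
proteins) is segmented as a 3D connected component per channel.  Two
shell statistics characterise its internal organisation:

* **autocorrelation g_a(r)** — the shell-binned intensity
  autocorrelation of a cluster divided by the same computation on a
  uniform-intensity object of identical shape (the support geometry
  cancels, so g_a reflects internal heterogeneity only; a uniform
  cluster gives g_a = 1 at all r, internal hotspots raise g_a at radii
  up to the hotspot size — the nanodomain size is read from where the
  curve flattens);
* **cross-enrichment** — the mean intensity of the measured cluster in
  shells around the *other* channel's intensity peak, normalized by the
  uniform surrogate; values > 1 at small r indicate trans-synaptic
  alignment of the two proteins' dense regions.

All distances are biological nm and honour anisotropic voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import next_fast_len, rfftn, irfftn

from .core import ImageStack, RadialCurve

__all__ = [
    "ClusterROI",
    "segment_synapses",
    "pair_clusters",
    "autocorrelation_ga",
    "autocorrelation_ga_bruteforce",
    "nanodomain_size",
    "cross_enrichment",
    "snr",
]

DEFAULT_SHELL_NM = 5.0


@dataclass
class ClusterROI:
    """A segmented 3D connected component (one synapse side).

    Arrays are cropped to the component's bounding box; ``origin``
    holds the global voxel index of the box corner.  ``peak_voxel`` is
    the global index of the intensity maximum after a 3-voxel median
    filter (suppresses single-voxel noise spikes).
    """

    mask: np.ndarray  # (dz, dy, dx) bool
    intensities: np.ndarray  # same shape; zero outside mask
    origin: tuple[int, int, int]
    voxel_size_nm: tuple[float, float, float]
    peak_voxel: tuple[int, int, int]  # global index
    channel: str = ""
    label: int = 0

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("empty ROI mask")
        pk = tuple(np.asarray(self.peak_voxel) - np.asarray(self.origin))
        if not self.mask[pk]:
            raise ValueError("peak_voxel outside mask")

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid_nm(self) -> np.ndarray:
        idx = np.argwhere(self.mask) + np.asarray(self.origin)
        return (idx * np.asarray(self.voxel_size_nm)).mean(axis=0)

    @property
    def mean_intensity(self) -> float:
        return float(self.intensities[self.mask].mean())


def _median3(vol: np.ndarray) -> np.ndarray:
    return ndimage.median_filter(vol, size=3)


def _make_roi(vol, labels, lab, voxel_size_nm, channel) -> ClusterROI:
    where = labels == lab
    sl = ndimage.find_objects(where.astype(np.int8))[0]
    mask = where[sl]
    inten = np.where(mask, vol[sl], 0.0)
    med = np.where(mask, _median3(vol[sl]), -np.inf)
    pk_local = np.unravel_index(np.argmax(med), med.shape)
    origin = tuple(s.start for s in sl)
    peak = tuple(int(o + p) for o, p in zip(origin, pk_local))
    return ClusterROI(mask, inten, origin, voxel_size_nm, peak, channel, int(lab))


def segment_synapses(
    stack: ImageStack,
    background_mask: np.ndarray | None = None,
    k_sigma: float = 7.0,
    n_keep: int | None = None,
    channel: str | int | None = None,
) -> list[ClusterROI]:
    """Threshold-and-label 3D segmentation of synaptic clusters.

    The binarisation threshold is ``background mean + k_sigma *
    background s.d.``; background statistics come from
    ``background_mask`` if given, otherwise from the voxels below the
    overall median (a conservative automatic stand-in for manually
    outlined background regions).  Components are 26-connected; the
    ``n_keep`` largest are returned, sorted by volume (descending).
    An image with nothing above threshold returns an empty list.
    """
    st = stack.channel(channel) if channel is not None else stack
    vol = np.asarray(st.voxels, dtype=float)
    if vol.ndim != 3:
        raise ValueError("segment_synapses expects a single-channel 3D stack")
    if background_mask is not None:
        bg = vol[background_mask]
        thr = float(bg.mean() + k_sigma * bg.std())
    else:
        # robust automatic background: median / MAD of the whole volume
        # (signal voxels are sparse, so both are background-dominated)
        med = float(np.median(vol))
        sd = 1.4826 * float(np.median(np.abs(vol - med)))
        thr = med + k_sigma * sd
    binary = vol > thr
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return []
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    if n_keep is not None:
        order = order[:n_keep]
    vsz = st.bio_pixel_size_nm
    ch_name = str(channel) if channel is not None else ""
    return [_make_roi(vol, labels, lab, vsz, ch_name) for lab in order]


def pair_clusters(
    rois_a: list[ClusterROI],
    rois_b: list[ClusterROI],
    max_distance_nm: float = 500.0,
) -> list[tuple[ClusterROI, ClusterROI]]:
    """Mutual-nearest-centroid pairing of clusters across two channels.

    Automates the manual identification of juxtaposed pre/post
    clusters: a pair is kept when each is the other's nearest centroid
    within ``max_distance_nm``.
    """
    if not rois_a or not rois_b:
        return []
    ca = np.array([r.centroid_nm for r in rois_a])
    cb = np.array([r.centroid_nm for r in rois_b])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    pairs = []
    for i in range(len(rois_a)):
        j = int(np.argmin(d[i]))
        if d[i, j] <= max_distance_nm and int(np.argmin(d[:, j])) == i:
            pairs.append((rois_a[i], rois_b[j]))
    return pairs


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------


def _shell_edges(max_r_nm: float, shell_nm: float) -> np.ndarray:
    return np.arange(0, max_r_nm + shell_nm, shell_nm)


def autocorrelation_ga(
    roi: ClusterROI,
    shell_nm: float = DEFAULT_SHELL_NM,
    max_radius_nm: float | None = None,
) -> RadialCurve:
    """Normalized 3D autocorrelation g_a(r) of a cluster.

    Computes, per distance shell, the mean product of intensities over
    all ordered voxel pairs of the cluster whose separation falls in
    the shell, divided by the same quantity for a uniform object of
    identical shape and mean intensity.  FFT-accelerated with explicit
    pair-count normalization; exact up to floating-point error (the
    brute-force pair enumeration is kept as
    :func:`autocorrelation_ga_bruteforce`).

    Shells with zero pairs are NaN with n = 0.
    """
    mask = roi.mask.astype(float)
    inten = np.where(roi.mask, roi.intensities, 0.0).astype(float)
    vsz = np.asarray(roi.voxel_size_nm, dtype=float)
    shape = mask.shape
    if max_radius_nm is None:
        max_radius_nm = float(np.linalg.norm((np.array(shape) - 1) * vsz))

    padded = [next_fast_len(2 * n - 1) for n in shape]
    fm = rfftn(mask, padded)
    fi = rfftn(inten, padded)
    corr_i = irfftn(fi * np.conj(fi), padded).real  # sum I(p)I(p+d) per lag d
    corr_m = irfftn(fm * np.conj(fm), padded).real  # ordered-pair counts per lag

    # lag distance per grid point (circular layout: index k -> lag k or k-m)
    lags = []
    for m, n, v in zip(padded, shape, vsz):
        k = np.arange(m)
        lag = np.where(k <= m // 2, k, k - m).astype(float)
        lags.append(lag * v)
    dist = np.sqrt(
        lags[0][:, None, None] ** 2
        + lags[1][None, :, None] ** 2
        + lags[2][None, None, :] ** 2
    )

    edges = _shell_edges(max_radius_nm, shell_nm)
    which = np.digitize(np.round(dist.ravel(), 6), edges) - 1
    nb = len(edges) - 1
    ok = (which >= 0) & (which < nb)
    sum_i = np.bincount(which[ok], corr_i.ravel()[ok], minlength=nb)
    sum_m = np.bincount(which[ok], corr_m.ravel()[ok], minlength=nb)
    mean_i = roi.mean_intensity
    with np.errstate(invalid="ignore", divide="ignore"):
        ga = sum_i / (mean_i**2 * sum_m)
    n_pairs = np.rint(sum_m).astype(np.int64)
    ga[n_pairs == 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialCurve(centers, ga, n_pairs, label="g_a")


def autocorrelation_ga_bruteforce(
    roi: ClusterROI, shell_nm: float = DEFAULT_SHELL_NM,
    max_radius_nm: float | None = None,
) -> RadialCurve:
    """Exhaustive ordered-pair enumeration oracle for g_a(r).

    Quadratic in voxel count; intended for small ROIs in tests.
    """
    idx = np.argwhere(roi.mask)
    pos = idx * np.asarray(roi.voxel_size_nm)
    vals = roi.intensities[tuple(idx.T)]
    if max_radius_nm is None:
        max_radius_nm = float(
            np.linalg.norm((np.array(roi.mask.shape) - 1) * roi.voxel_size_nm)
        )
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1).ravel()
    prod = np.outer(vals, vals).ravel()
    edges = _shell_edges(max_radius_nm, shell_nm)
    which = np.digitize(np.round(d, 6), edges) - 1
    nb = len(edges) - 1
    ok = (which >= 0) & (which < nb)
    sum_i = np.bincount(which[ok], prod[ok], minlength=nb)
    counts = np.bincount(which[ok], minlength=nb)
    mean_i = vals.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        ga = sum_i / (mean_i**2 * counts)
    ga[counts == 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialCurve(centers, ga, counts, label="g_a")


def nanodomain_size(
    curve: RadialCurve,
    method: str = "flatten",
    flatten_tolerance_per_nm: float = 0.001,
    smooth_bins: int = 3,
    min_contrast: float = 0.02,
) -> tuple[float, bool]:
    """Nanodomain size from the decay of g_a(r).

    Returns ``(size_nm, defined)``.  ``method='flatten'`` (default)
    returns the first radius past the curve's peak where the smoothed
    derivative of g_a exceeds ``-flatten_tolerance_per_nm``, i.e. where
    the decay has stopped; on rendered synapse phantoms this tracks the
    (PSF-broadened) hotspot FWHM.  ``method='half_decay'`` instead
    reads the radius where the excess correlation g_a(r) - 1 has
    decayed to half its peak value, scaled by sqrt(2) (the FWHM of a
    Gaussian-shaped correlation excess); it is cheaper to reason about
    analytically but sensitive to the below-baseline dip that compact
    clusters produce at large radii.

    A curve with no contrast (max g_a < 1 + min_contrast) has no
    nanodomain: ``(0.0, False)``.  A curve still decaying at its last
    shell returns ``(nan, False)``.
    """
    if method not in ("half_decay", "flatten"):
        raise ValueError(f"unknown method {method!r}")
    r = curve.radii
    g = curve.values
    finite = np.isfinite(g)
    if finite.sum() < 5:
        raise ValueError("need at least 5 finite shells")
    r, g = r[finite], g[finite]
    if np.nanmax(g) < 1.0 + min_contrast:
        return 0.0, False
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        pad = smooth_bins // 2
        g = np.convolve(np.pad(g, pad, mode="edge"), kernel, mode="valid")[: r.size]
    ipk = int(np.argmax(g))
    if method == "flatten":
        dg = np.gradient(g, r)
        flat = np.flatnonzero(dg[ipk + 1 :] > -flatten_tolerance_per_nm)
        if flat.size == 0:
            return float("nan"), False
        return float(r[ipk + 1 + flat[0]]), True
    excess = g - 1.0
    target = 0.5 * excess[ipk]
    below = np.flatnonzero(excess[ipk:] <= target)
    if below.size == 0:
        return float("nan"), False
    i = ipk + below[0]
    if i == ipk:
        return float(np.sqrt(2.0) * r[i]), True
    # linear interpolation between the bracketing shells
    r_half = r[i - 1] + (excess[i - 1] - target) / (excess[i - 1] - excess[i]) * (
        r[i] - r[i - 1]
    )
    return float(np.sqrt(2.0) * r_half), True


# ---------------------------------------------------------------------------
# cross-enrichment
# ---------------------------------------------------------------------------


def cross_enrichment(
    measured: ClusterROI,
    reference: ClusterROI,
    shell_nm: float = DEFAULT_SHELL_NM,
    max_radius_nm: float = 200.0,
    align: str = "centroid",
) -> RadialCurve:
    """Enrichment of the measured cluster around the reference peak.

    Shell-averaged intensity of the measured cluster at distance r from
    the reference cluster's peak, normalized by the uniform surrogate
    (same shape and volume, constant mean intensity) — i.e. divided by
    the measured cluster's mean intensity wherever the shell intersects
    its mask.  Shells that miss the mask entirely are NaN.

    With ``align='centroid'`` (default) the reference cluster is first
    shifted across the cleft by the vector between the two clusters'
    centroids, so its peak is measured against the juxtaposed region of
    the measured cluster; a perfectly aligned nanocolumn then peaks at
    r = 0.  ``align='none'`` uses the raw peak position.
    """
    if measured.voxel_size_nm != reference.voxel_size_nm:
        raise ValueError("clusters must share a voxel grid")
    if align not in ("centroid", "none"):
        raise ValueError(f"unknown align {align!r}")
    vsz = np.asarray(measured.voxel_size_nm)
    peak_nm = np.asarray(reference.peak_voxel) * vsz
    if align == "centroid":
        peak_nm = peak_nm + (measured.centroid_nm - reference.centroid_nm)
    idx = np.argwhere(measured.mask) + np.asarray(measured.origin)
    pos = idx * vsz
    vals = measured.intensities[measured.mask]
    d = np.linalg.norm(pos - peak_nm, axis=1)
    edges = _shell_edges(max_radius_nm, shell_nm)
    which = np.digitize(d, edges) - 1
    nb = len(edges) - 1
    ok = (which >= 0) & (which < nb)
    sums = np.bincount(which[ok], vals[ok], minlength=nb)
    counts = np.bincount(which[ok], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        enrich = (sums / counts) / measured.mean_intensity
    enrich[counts == 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialCurve(centers, enrich, counts, label="enrichment")


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------


def snr(
    stack: ImageStack,
    rois: list[ClusterROI],
    background_mask: np.ndarray,
    channel: str | int | None = None,
) -> list[float]:
    """Per-ROI signal-to-noise ratio.

    Signal = mean ROI intensity; noise = s.d. of the background voxels.
    The stack should already be background-subtracted (see
    :func:`exmqc.core.preprocess`).
    """
    st = stack.channel(channel) if channel is not None else stack
    vol = np.asarray(st.voxels, dtype=float)
    bg = vol[background_mask]
    sd = float(bg.std())
    if sd == 0:
        raise ValueError("zero background variance")
    for roi in rois:
        sl = tuple(
            slice(o, o + s) for o, s in zip(roi.origin, roi.mask.shape)
        )
        if background_mask[sl][roi.mask].any():
            raise ValueError("background mask overlaps an ROI")
    return [roi.mean_intensity / sd for roi in rois]
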