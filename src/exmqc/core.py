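"""Core carriers and calibration for expanded-specimen image analysis.

Every quantitative module in this package works in *biological units*:
physical distances divided by the linear expansion factor, so that all
reported nanometre quantities refer to the original (unexpanded) specimen.
:class:`ImageStack` is the universal carrier holding the voxel grid, the
per-axis physical pixel size at the detector and the expansion factor.

Also provided here: landmark-based expansion-factor estimation, the
standard preprocessing chain (rolling-ball background subtraction,
Gaussian smoothing, maximum-intensity z-projection) and TIFF/OME-TIFF
round-trip I/O with pixel-size metadata.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.restoration import rolling_ball

__all__ = [
    "ImageStack",
    "LandmarkPairSet",
    "RadialCurve",
    "MetadataError",
    "read_stack",
    "write_stack",
    "read_landmarks",
    "expansion_factor_from_landmarks",
    "preprocess",
]


class MetadataError(ValueError):
    """Raised when pixel-size metadata is missing or contradictory."""


@dataclass
class ImageStack:
    """N-D intensity image with physical sampling and expansion factor.

    Parameters
    ----------
    voxels
        2D ``(y, x)``, 3D ``(z, y, x)`` or channel-first
        ``(c, ...)`` intensity array (set ``channel_names`` to mark a
        leading channel axis).
    pixel_size_nm
        Per-spatial-axis sampling at the detector, i.e. *physical*
        nanometres per voxel, before division by the expansion factor.
    expansion_factor
        Linear expansion factor (>= 1); 1 for unexpanded data.
    channel_names
        Labels for a leading channel axis, or None for single-channel.
    """

    voxels: np.ndarray
    pixel_size_nm: tuple[float, ...]
    expansion_factor: float = 1.0
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if np.isscalar(self.pixel_size_nm):
            ndim_spatial = self.voxels.ndim - (1 if self.channel_names else 0)
            self.pixel_size_nm = (float(self.pixel_size_nm),) * ndim_spatial
        else:
            self.pixel_size_nm = tuple(float(p) for p in self.pixel_size_nm)
        if any(p <= 0 for p in self.pixel_size_nm):
            raise ValueError("pixel sizes must be positive")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        n_spatial = len(self.pixel_size_nm)
        expected = n_spatial + (1 if self.channel_names else 0)
        if self.voxels.ndim != expected:
            raise ValueError(
                f"voxels ndim {self.voxels.ndim} does not match "
                f"{n_spatial} spatial axes"
                + (" plus channel axis" if self.channel_names else "")
            )
        if self.channel_names is not None:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.voxels.shape[0]:
                raise ValueError("channel_names length mismatch")

    # -- derived geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return 1 if self.channel_names is None else self.voxels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.voxels.shape[1:] if self.channel_names else self.voxels.shape

    @property
    def bio_pixel_size_nm(self) -> tuple[float, ...]:
        """Sampling in biological units: physical size / expansion factor."""
        return tuple(p / self.expansion_factor for p in self.pixel_size_nm)

    def channel(self, name_or_index: str | int) -> "ImageStack":
        """Single-channel view of a multi-channel stack."""
        if self.channel_names is None:
            raise ValueError("stack has no channel axis")
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return ImageStack(
            self.voxels[idx], self.pixel_size_nm, self.expansion_factor, None
        )

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(
            voxels, self.pixel_size_nm, self.expansion_factor, self.channel_names
        )


@dataclass
class RadialCurve:
    """Generic (radius, value) series.

    Used for autocorrelation g_a(r), cross-enrichment, NPC radial
    profiles (radius in nm) and FRC curves (radius in cycles/nm).
    """

    radii: np.ndarray
    values: np.ndarray
    n: np.ndarray | None = None  # samples (voxels, pairs or Fourier bins) per bin
    label: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii.shape != self.values.shape:
            raise ValueError("radii and values must have the same shape")

    def to_frame(self) -> pd.DataFrame:
        d = {"radius": self.radii, "value": self.values}
        if self.n is not None:
            d["n"] = self.n
        return pd.DataFrame(d)


@dataclass
class LandmarkPairSet:
    """Matched pre-/post-expansion landmark coordinates (physical nm)."""

    pre_points: np.ndarray  # (n, d)
    post_points: np.ndarray  # (n, d)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pre_points = np.atleast_2d(np.asarray(self.pre_points, dtype=float))
        self.post_points = np.atleast_2d(np.asarray(self.post_points, dtype=float))
        if self.pre_points.shape != self.post_points.shape:
            raise ValueError("pre/post point sets must match in shape")
        if len(self.pre_points) < 2:
            raise ValueError("need at least 2 matched landmarks")


def read_landmarks(path: str | Path) -> LandmarkPairSet:
    """Read a landmark CSV with columns id, pre_x, pre_y[, pre_z], post_x, ...

    Coordinates are physical nanometres.
    """
    df = pd.read_csv(path)
    axes = [a for a in ("x", "y", "z") if f"pre_{a}" in df.columns]
    if not axes:
        raise MetadataError(f"{path}: no pre_x/pre_y coordinate columns found")
    pre = df[[f"pre_{a}" for a in axes]].to_numpy(dtype=float)
    post = df[[f"post_{a}" for a in axes]].to_numpy(dtype=float)
    labels = [str(v) for v in df["id"]] if "id" in df.columns else []
    return LandmarkPairSet(pre, post, labels)


def expansion_factor_from_landmarks(
    pairs: LandmarkPairSet,
) -> tuple[float, float, np.ndarray]:
    """Estimate the linear expansion factor from matched landmarks.

    Every unordered pair of landmarks contributes one ratio
    ``post_distance / pre_distance``; the summary is the mean and sample
    s.d. over those ratios.  Invariant under rigid motion of either
    point set.

    Returns
    -------
    (mean_factor, sd_factor, per_pair_ratios)
    """
    pre, post = pairs.pre_points, pairs.post_points
    n = len(pre)
    iu = np.triu_indices(n, k=1)
    d_pre = np.linalg.norm(pre[iu[0]] - pre[iu[1]], axis=1)
    d_post = np.linalg.norm(post[iu[0]] - post[iu[1]], axis=1)
    if np.any(d_pre == 0):
        raise ValueError("zero pre-expansion landmark distance")
    ratios = d_post / d_pre
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return float(np.mean(ratios)), sd, ratios


def _rolling_ball_2d(plane: np.ndarray, radius: int) -> np.ndarray:
    background = rolling_ball(plane, radius=radius)
    return np.clip(plane - background, 0, None)


def preprocess(
    stack: ImageStack,
    rolling_ball_radius_px: int = 50,
    gaussian_sigma_px: float = 0.0,
    max_project: bool = False,
) -> ImageStack:
    """Standard preprocessing chain for expanded-specimen confocal images.

    Applies, in order: per-plane rolling-ball background subtraction
    (radius in pixels; 0 disables), Gaussian smoothing (sigma in pixels;
    0 disables) and optional maximum-intensity projection along z.
    Output is clamped at zero (rolling-ball convention).
    """
    if rolling_ball_radius_px < 0 or gaussian_sigma_px < 0:
        raise ValueError("radius and sigma must be >= 0")
    if rolling_ball_radius_px > max(stack.spatial_shape):
        raise ValueError("rolling-ball radius exceeds image extent")

    def _per_channel(img: np.ndarray) -> np.ndarray:
        out = img.astype(float, copy=True)
        if rolling_ball_radius_px > 0:
            if out.ndim == 2:
                out = _rolling_ball_2d(out, rolling_ball_radius_px)
            else:
                out = np.stack(
                    [_rolling_ball_2d(p, rolling_ball_radius_px) for p in out]
                )
        if gaussian_sigma_px > 0:
            if out.ndim == 3:
                # 2D filter per z-plane, matching the 2D convention
                out = ndimage.gaussian_filter(
                    out, (0, gaussian_sigma_px, gaussian_sigma_px)
                )
            else:
                out = ndimage.gaussian_filter(out, gaussian_sigma_px)
        if max_project and out.ndim == 3:
            out = out.max(axis=0)
        return out

    if stack.channel_names:
        vox = np.stack([_per_channel(stack.voxels[c]) for c in range(stack.n_channels)])
    else:
        vox = _per_channel(stack.voxels)
    px = stack.pixel_size_nm
    if max_project and len(stack.spatial_shape) == 3:
        px = px[1:]
    return ImageStack(vox, px, stack.expansion_factor, stack.channel_names)


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF I/O
# ---------------------------------------------------------------------------

_OME_UNIT_TO_NM = {"nm": 1.0, "µm": 1e3, "um": 1e3, "micron": 1e3, "mm": 1e6}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an OME-TIFF with PhysicalSize metadata (nm) plus a JSON sidecar.

    The sidecar records the expansion factor and channel names, which
    OME pixel metadata has no standard slot for.
    """
    path = Path(path)
    vox = stack.voxels
    nd = len(stack.spatial_shape)
    axes = ("C" if stack.channel_names else "") + ("ZYX" if nd == 3 else "YX")
    meta: dict = {"axes": axes}
    # pixel_size_nm is ordered like the spatial axes (z, y, x) / (y, x)
    meta["PhysicalSizeX"] = stack.pixel_size_nm[-1]
    meta["PhysicalSizeXUnit"] = "nm"
    meta["PhysicalSizeY"] = stack.pixel_size_nm[-2]
    meta["PhysicalSizeYUnit"] = "nm"
    if nd == 3:
        meta["PhysicalSizeZ"] = stack.pixel_size_nm[0]
        meta["PhysicalSizeZUnit"] = "nm"
    tifffile.imwrite(path, vox.astype(np.float32), ome=True, metadata=meta)
    sidecar = {
        "expansion_factor": stack.expansion_factor,
        "channel_names": list(stack.channel_names) if stack.channel_names else None,
        "pixel_size_nm": list(stack.pixel_size_nm),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _pixel_size_from_ome(xml: str, axis: str) -> float | None:
    m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', xml)
    if not m:
        return None
    value = float(m.group(1))
    mu = re.search(rf'PhysicalSize{axis}Unit="([^"]+)"', xml)
    unit = mu.group(1) if mu else "µm"
    if unit not in _OME_UNIT_TO_NM:
        raise MetadataError(f"unsupported OME unit {unit!r}")
    return value * _OME_UNIT_TO_NM[unit]


def read_stack(
    path: str | Path,
    pixel_size_override_nm: float | tuple[float, ...] | None = None,
    expansion_factor: float | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Pixel size comes from OME metadata unless overridden; a plain TIFF
    with no metadata and no override raises :class:`MetadataError`.
    The expansion factor comes from the argument, else the JSON sidecar
    written by :func:`write_stack`, else defaults to 1 with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        vox = tf.asarray()
        ome = tf.ome_metadata

    sidecar = None
    sp = _sidecar_path(path)
    if sp.exists():
        sidecar = json.loads(sp.read_text())

    channel_names = None
    nd_spatial = vox.ndim
    if sidecar and sidecar.get("channel_names"):
        channel_names = tuple(sidecar["channel_names"])
        nd_spatial = vox.ndim - 1

    if pixel_size_override_nm is not None:
        px = pixel_size_override_nm
        if np.isscalar(px):
            px = (float(px),) * nd_spatial
    elif ome:
        sx = _pixel_size_from_ome(ome, "X")
        sy = _pixel_size_from_ome(ome, "Y")
        sz = _pixel_size_from_ome(ome, "Z")
        if sx is None or sy is None:
            raise MetadataError(f"{path}: OME metadata lacks pixel size")
        px = (sz, sy, sx) if nd_spatial == 3 else (sy, sx)
        if nd_spatial == 3 and sz is None:
            raise MetadataError(f"{path}: 3D stack without PhysicalSizeZ")
    else:
        raise MetadataError(
            f"{path}: no pixel-size metadata; pass pixel_size_override_nm"
        )

    if expansion_factor is None:
        if sidecar and sidecar.get("expansion_factor"):
            expansion_factor = float(sidecar["expansion_factor"])
        else:
            warnings.warn(f"{path}: no expansion factor; assuming 1.0")
            expansion_factor = 1.0

    return ImageStack(vox, px, expansion_factor, channel_names)
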