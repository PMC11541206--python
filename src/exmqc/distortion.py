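"""Pre-/post-expansion registration and r.m.s. distortion analysis.

Expansion distortion is quantified by registering a pre-expansion image
to the post-expansion image of the same field (rescaled into biological
units), first rigidly (similarity: translation + rotation + isotropic
scale — the recovered scale is itself an expansion-factor estimate),
then nonrigidly with a multiresolution B-spline free-form deformation.
The residual deformation vector field gives the r.m.s. measurement
error as a function of measurement length: for point pairs a distance L
apart, the r.m.s. difference between their deformed and undeformed
separations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import ImageStack

__all__ = [
    "RegistrationError",
    "RigidResult",
    "DeformationField",
    "RmsCurve",
    "rigid_register",
    "nonrigid_register",
    "rms_error_curve",
    "default_lengths_nm",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class RigidResult:
    """Similarity pre-registration outcome.

    ``scale`` multiplies post distances to match pre distances *after*
    both are already in biological units, so it is a residual
    expansion-factor correction (1.0 when the nominal factor is exact).
    """

    translation_nm: tuple[float, float]
    rotation_deg: float
    scale: float
    correlation: float
    post_aligned: ImageStack
    transform: object  # sitk.Transform


@dataclass
class DeformationField:
    """Residual nonrigid displacement, biological nm.

    ``displacement_nm[..., (0, 1)]`` are (uy, ux) per pixel of the
    rigid-aligned post image: the vector from each post pixel to its
    corresponding pre-image point, ``pre(x + u(x)) ~ post_aligned(x)``.
    """

    displacement_nm: np.ndarray  # (H, W, 2)
    pixel_size_nm: tuple[float, float]
    valid_mask: np.ndarray  # (H, W) bool

    @property
    def rms_nm(self) -> float:
        mag2 = np.sum(self.displacement_nm**2, axis=-1)
        return float(np.sqrt(mag2[self.valid_mask].mean()))

    def sample_nm(self, points_nm: np.ndarray) -> np.ndarray:
        """Bilinear displacement at (y, x) nm points, shape (n, 2)."""
        py, px = self.pixel_size_nm
        iy = points_nm[:, 0] / py
        ix = points_nm[:, 1] / px
        uy = ndimage.map_coordinates(
            self.displacement_nm[..., 0], [iy, ix], order=1, mode="nearest"
        )
        ux = ndimage.map_coordinates(
            self.displacement_nm[..., 1], [iy, ix], order=1, mode="nearest"
        )
        return np.stack([uy, ux], axis=-1)


@dataclass
class RmsCurve:
    lengths_nm: np.ndarray
    rms_nm: np.ndarray
    sd_nm: np.ndarray
    n_pairs: np.ndarray


def _to_sitk(stack: ImageStack) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(stack.voxels, dtype=np.float64))
    py, px = stack.bio_pixel_size_nm
    img.SetSpacing((px, py))  # sitk order is (x, y)
    return img


def rigid_register(
    pre: ImageStack, post: ImageStack, min_correlation: float = 0.2
) -> RigidResult:
    """Similarity registration of the post image onto the pre image.

    Both images are interpreted on their biological-unit grids (the
    expansion factor has already rescaled the post pixel size), so the
    remaining transform is a small similarity.  Uses a multiresolution
    correlation-metric optimization; raises
    :class:`RegistrationError` when the final correlation is below
    ``min_correlation``.
    """
    fixed = _to_sitk(pre)
    moving = _to_sitk(post)
    tx0 = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Similarity2DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-6, numberOfIterations=500,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2, 1, 0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(tx0, inPlace=True)
    try:
        tx = reg.Execute(fixed, moving)
    except RuntimeError as e:  # pragma: no cover - sitk internal failure
        raise RegistrationError(str(e)) from e
    corr = -reg.GetMetricValue()  # sitk minimizes the negative correlation
    if corr < min_correlation:
        raise RegistrationError(
            f"rigid registration failed: correlation {corr:.3f} < {min_correlation}"
        )
    sim = sitk.Similarity2DTransform(tx)
    aligned = sitk.Resample(moving, fixed, tx, sitk.sitkLinear, 0.0)
    post_aligned = ImageStack(
        sitk.GetArrayFromImage(aligned),
        pre.pixel_size_nm,
        pre.expansion_factor,
    )
    t = sim.GetTranslation()
    return RigidResult(
        translation_nm=(float(t[1]), float(t[0])),
        rotation_deg=float(np.rad2deg(sim.GetAngle())),
        scale=float(sim.GetScale()),
        correlation=float(corr),
        post_aligned=post_aligned,
        transform=tx,
    )


def _bspline_stage(fixed, moving, control_spacing_px, iterations) -> np.ndarray:
    """One B-spline FFD stage; returns the (H, W, (uy, ux)) field in nm."""
    size = np.array(fixed.GetSize())  # (x, y)
    mesh = [int(m) for m in np.maximum(size // control_spacing_px, 1)]
    bspline = sitk.BSplineTransformInitializer(fixed, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7, numberOfIterations=iterations
    )
    reg.SetInitialTransform(bspline, inPlace=True)
    try:
        reg.Execute(fixed, moving)
    except RuntimeError as e:
        raise RegistrationError(f"nonrigid registration failed: {e}") from e
    f2d = sitk.TransformToDisplacementFieldFilter()
    f2d.SetReferenceImage(fixed)
    disp = sitk.GetArrayFromImage(f2d.Execute(bspline))  # (H, W, (dx, dy))
    return disp[..., ::-1]  # (uy, ux), physical (nm) units


def nonrigid_register(
    pre: ImageStack,
    post_aligned: ImageStack,
    preprocess_sigma_px: float = 4.0,
    control_spacing_px: tuple[int, ...] = (16,),
    border_px: int = 8,
    iterations: int = 100,
) -> DeformationField:
    """Residual nonrigid deformation between rigid-aligned images.

    Both inputs are Gaussian-presmoothed (sigma in pixels) and z-scored,
    then a B-spline free-form deformation minimizing the mean-squared
    difference (equivalent to maximizing correlation after the
    normalization) is fitted with L-BFGS-B; the control-point spacing
    acts as the smoothness regularizer.  Passing several spacings runs
    coarse-to-fine stages, resampling between stages and composing the
    fields.  The returned field maps post_aligned pixel positions to
    their pre-image locations (``pre(x + u(x)) ~ post_aligned(x)``) in
    biological nm; ``valid_mask`` excludes a ``border_px`` frame where
    the field is extrapolated.
    """
    if pre.spatial_shape != post_aligned.spatial_shape:
        raise ValueError("inputs must share a grid (run rigid_register first)")

    def _smoothed(arr):
        v = ndimage.gaussian_filter(np.asarray(arr, dtype=float), preprocess_sigma_px)
        # z-score so the mean-squares metric behaves like a correlation
        # (the ITK correlation metric does not support B-spline transforms)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    # fixed = post_aligned so the field lives on post coordinates
    fixed_arr = _smoothed(post_aligned.voxels)
    moving_arr = _smoothed(pre.voxels)
    py, px = post_aligned.bio_pixel_size_nm

    def _as_sitk(a):
        img = sitk.GetImageFromArray(a)
        img.SetSpacing((px, py))
        return img

    h, w = fixed_arr.shape
    u_total = np.zeros((h, w, 2))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for sp in control_spacing_px:
        # current residual moving image: pre sampled through u_total
        if np.any(u_total):
            cy = yy + u_total[..., 0] / py
            cx = xx + u_total[..., 1] / px
            cur = ndimage.map_coordinates(moving_arr, [cy, cx], order=1,
                                          mode="nearest")
        else:
            cur = moving_arr
        du = _bspline_stage(_as_sitk(fixed_arr), _as_sitk(cur), sp, iterations)
        u_total += du
    valid = np.zeros((h, w), dtype=bool)
    b = border_px
    valid[b : h - b, b : w - b] = True
    return DeformationField(u_total, (py, px), valid)


def default_lengths_nm(max_nm: float, n: int = 10, min_nm: float = 100.0):
    """Log-spaced measurement lengths from min_nm up to the field extent."""
    return np.geomspace(min_nm, max_nm, n)


def rms_error_curve(
    field: DeformationField,
    lengths_nm,
    n_samples: int = 1000,
    seed: int = 0,
) -> RmsCurve:
    """r.m.s. measurement error vs measurement length.

    For each length L, samples ``n_samples`` point pairs (p, q) with
    |p - q| = L, uniformly positioned and oriented inside the valid
    mask, and evaluates ``|(q + u(q)) - (p + u(p))| - L``: the change a
    distance measurement of length L suffers under the deformation.
    rms(0) = 0 by construction; a pure translation field scores 0 at
    every length (gauge invariance).
    """
    lengths_nm = np.atleast_1d(np.asarray(lengths_nm, dtype=float))
    rng = np.random.default_rng(seed)
    h, w = field.valid_mask.shape
    py, px = field.pixel_size_nm
    extent = np.array([(h - 1) * py, (w - 1) * px])
    valid_idx = np.argwhere(field.valid_mask)
    if valid_idx.size == 0:
        raise ValueError("empty valid mask")

    rms, sd, n_used = [], [], []
    for L in lengths_nm:
        if L > min(extent):
            raise ValueError(f"length {L} nm exceeds field extent {extent}")
        errors = np.empty(0)
        attempts = 0
        while errors.size < n_samples and attempts < 20:
            m = (n_samples - errors.size) * 2
            p = valid_idx[rng.integers(0, len(valid_idx), m)] * (py, px)
            theta = rng.uniform(0, 2 * np.pi, m)
            q = p + L * np.stack([np.sin(theta), np.cos(theta)], axis=-1)
            iy, ix = q[:, 0] / py, q[:, 1] / px
            ok = (iy >= 0) & (iy <= h - 1) & (ix >= 0) & (ix <= w - 1)
            ok &= field.valid_mask[
                np.clip(np.rint(iy).astype(int), 0, h - 1),
                np.clip(np.rint(ix).astype(int), 0, w - 1),
            ]
            p, q = p[ok], q[ok]
            if p.size:
                up = field.sample_nm(p)
                uq = field.sample_nm(q)
                err = np.linalg.norm((q + uq) - (p + up), axis=1) - L
                errors = np.concatenate([errors, err])
            attempts += 1
        if errors.size == 0:
            raise ValueError(f"no valid pairs at length {L} nm")
        errors = errors[:n_samples]
        rms.append(float(np.sqrt(np.mean(errors**2))))
        sd.append(float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0)
        n_used.append(errors.size)
    return RmsCurve(lengths_nm, np.array(rms), np.array(sd), np.array(n_used))
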