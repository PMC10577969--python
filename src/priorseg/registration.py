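"""Deformable registration of pre- to post-operative CT and mask warping.

Registration aligns the preoperative (moving) scan with the postoperative
(fixed) scan and returns a dense deformation vector field (DVF): one
displacement vector in mm per fixed-grid voxel. The field follows the
*pull* convention — to produce a warped image on the fixed grid, each fixed
voxel at physical position x samples the moving image at x + u(x). That is
the direction needed to carry a preoperative contour (EV_1cm) into the
postoperative frame.

The algorithm is a multi-resolution demons registration with Gaussian
field smoothing under a sum-of-squared-differences criterion — appropriate
for same-modality CT pairs — run via SimpleITK's demons filters. It is
fully deterministic: the optimization has no random component.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volumes import AIR_HU, BinaryMask, GridMismatchError, ImageVolume


@dataclasses.dataclass(frozen=True)
class RegistrationParams:
    """Demons registration settings.

    pyramid_levels
        Number of resolution levels (coarse to fine); in-plane shrink
        halves per level, the slice axis is shrunk less (slices are thick).
    iterations_per_level
        Demons iterations at each level.
    smoothing_sigma_mm
        Gaussian smoothing of the displacement field, in mm.
    step_size
        Maximum update step length in voxel units per iteration.
    metric
        Only "SSD" (the demons criterion) is supported.
    """

    pyramid_levels: int = 3
    iterations_per_level: int = 40
    smoothing_sigma_mm: float = 2.0
    step_size: float = 1.0
    metric: str = "SSD"

    def __post_init__(self):
        if self.pyramid_levels < 1 or self.iterations_per_level < 1:
            raise ValueError("pyramid_levels and iterations_per_level must be >= 1")
        if self.smoothing_sigma_mm < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.metric != "SSD":
            raise ValueError(f"unsupported metric {self.metric!r}")


@dataclasses.dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm) on the fixed image's grid.

    ``displacements`` has shape ``(nx, ny, nz, 3)``; the last axis holds
    the (ux, uy, uz) components in mm.
    """

    displacements: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=np.float32)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError(
                f"displacements must have shape (nx,ny,nz,3), got {self.displacements.shape}"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement components must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    @classmethod
    def zero(cls, like: ImageVolume) -> "DeformationField":
        return cls(
            np.zeros(like.shape + (3,), dtype=np.float32), like.spacing, like.origin
        )

    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.displacements.astype(np.float64) ** 2).sum(-1)).max())


# ---------------------------------------------------------------------------
# SimpleITK conversion helpers (sitk arrays are indexed (z, y, x))


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.T, dtype=np.float32))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def _field_from_sitk(field: sitk.Image, like: ImageVolume) -> DeformationField:
    arr = sitk.GetArrayFromImage(field)  # (nz, ny, nx, 3), components (x, y, z) in mm
    disp = np.ascontiguousarray(arr.transpose(2, 1, 0, 3)).astype(np.float32)
    return DeformationField(disp, like.spacing, like.origin)


def _check_same_grid(a, b, what: str):
    if not a.same_grid(b):
        raise GridMismatchError(f"{what}: grids differ (shapes {a.shape} vs {b.shape})")


# ---------------------------------------------------------------------------
# Warping (pull convention, scipy resampler)


def _warp_array(
    data: np.ndarray,
    dvf: DeformationField,
    order: int,
    cval: float,
) -> np.ndarray:
    spacing = np.array(dvf.spacing)
    idx = np.indices(dvf.shape, dtype=np.float32)
    # sample position in voxel units: index + displacement / spacing
    coords = idx + np.moveaxis(dvf.displacements, -1, 0) / spacing[:, None, None, None]
    return ndimage.map_coordinates(
        data.astype(np.float32), coords, order=order, mode="constant", cval=cval
    )


def warp_volume(vol: ImageVolume, dvf: DeformationField) -> ImageVolume:
    """Resample an image through a deformation field (linear interpolation).

    Out-of-bounds samples are filled with air (−1024 HU).
    """
    if vol.shape != dvf.shape:
        raise GridMismatchError(f"volume {vol.shape} vs field {dvf.shape}")
    out = _warp_array(vol.voxels, dvf, order=1, cval=AIR_HU)
    return ImageVolume(out, dvf.spacing, dvf.origin)


def warp_mask(mask: BinaryMask, dvf: DeformationField) -> BinaryMask:
    """Carry a binary mask through a deformation field.

    The mask is sampled with linear interpolation and re-binarized at 0.5,
    which gives smoother warped boundaries than nearest-neighbor sampling.
    """
    if mask.shape != dvf.shape:
        raise GridMismatchError(f"mask {mask.shape} vs field {dvf.shape}")
    out = _warp_array(mask.voxels.astype(np.float32), dvf, order=1, cval=0.0)
    return BinaryMask(out >= 0.5, dvf.spacing, dvf.origin, label=mask.label)


def ssd(a: ImageVolume, b: ImageVolume) -> float:
    """Sum of squared intensity differences (the registration criterion)."""
    _check_same_grid(a, b, "ssd")
    d = a.voxels.astype(np.float64) - b.voxels.astype(np.float64)
    return float((d * d).sum())


# ---------------------------------------------------------------------------
# Registration


def _shrink_factors(shape, level: int, n_levels: int) -> list[int]:
    """Per-axis shrink for a pyramid level, never reducing an axis below 8."""
    f = 2 ** (n_levels - 1 - level)
    return [max(1, min(f, s // 8)) if s >= 8 else 1 for s in shape]


def _smooth_and_shrink(img: sitk.Image, factors) -> sitk.Image:
    if all(f == 1 for f in factors):
        return img
    sigmas = [
        0.5 * f * sp if f > 1 else 1e-8 for f, sp in zip(factors, img.GetSpacing())
    ]
    smoothed = sitk.SmoothingRecursiveGaussian(img, sigmas)
    new_size = [max(1, int(s // f)) for s, f in zip(img.GetSize(), factors)]
    new_spacing = [sp * s / ns for sp, s, ns in zip(img.GetSpacing(), img.GetSize(), new_size)]
    ref = sitk.Image(new_size, img.GetPixelID())
    ref.SetSpacing(new_spacing)
    ref.SetOrigin(img.GetOrigin())
    ref.SetDirection(img.GetDirection())
    return sitk.Resample(smoothed, ref, sitk.Transform(), sitk.sitkLinear, 0.0)


def register_deformable(
    fixed: ImageVolume,
    moving: ImageVolume,
    params: RegistrationParams | None = None,
) -> DeformationField:
    """Estimate the dense deformation aligning ``moving`` to ``fixed``.

    Multi-resolution symmetric-forces demons: at each pyramid level the
    displacement field estimated so far is upsampled and refined. Given
    identical inputs and parameters the result is bit-reproducible.
    """
    params = params or RegistrationParams()
    _check_same_grid(fixed, moving, "register_deformable")
    if not (np.all(np.isfinite(fixed.voxels)) and np.all(np.isfinite(moving.voxels))):
        raise ValueError("non-finite voxel values in registration input")

    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(params.iterations_per_level)
    demons.SetSmoothDisplacementField(True)
    demons.SetMaximumUpdateStepLength(params.step_size)

    field = None
    for level in range(params.pyramid_levels):
        factors = _shrink_factors(fixed.shape, level, params.pyramid_levels)
        f_lvl = _smooth_and_shrink(f_img, factors)
        m_lvl = _smooth_and_shrink(m_img, factors)
        # field smoothing sigma is set in voxel units of the current level
        sigmas = [
            max(params.smoothing_sigma_mm / sp, 0.1) for sp in f_lvl.GetSpacing()
        ]
        demons.SetStandardDeviations(sigmas)
        if field is None:
            field = sitk.Image(f_lvl.GetSize(), sitk.sitkVectorFloat64, 3)
            field.CopyInformation(f_lvl)
        else:
            field = sitk.Resample(field, f_lvl, sitk.Transform(), sitk.sitkLinear)
            field = sitk.Cast(field, sitk.sitkVectorFloat64)
        field = demons.Execute(f_lvl, m_lvl, field)

    field = sitk.Resample(field, f_img, sitk.Transform(), sitk.sitkLinear)
    return _field_from_sitk(field, fixed)
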