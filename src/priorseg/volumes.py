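"""Volume and mask containers plus grid-level preprocessing.

The package works on 3D CT volumes in Hounsfield units (HU) together with
binary region-of-interest (ROI) masks defined on the same voxel grid.
Arrays are indexed ``[i, j, k]`` with ``i`` the fastest in-plane axis and
``k`` the slice axis; the physical center of voxel ``(i, j, k)`` is
``origin + (i*dx, j*dy, k*dz)`` with all distances in millimetres.

I/O is NIfTI-1 via nibabel; masks are stored as uint8 {0, 1} volumes.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

AIR_HU = -1024.0

#: ROI names used throughout the pipeline.
ROI_LABELS = ("PT", "EV", "EV_1cm", "T-EV_1cm", "TB", "CTV-TB", "BREAST", "PREDICTED")


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


class DegenerateInputError(ValueError):
    """An operation received an input it is undefined for (e.g. empty mask)."""


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar image (HU) on a regular grid with physical spacing.

    Parameters
    ----------
    voxels
        3D array of intensities, indexed ``[i, j, k]``.
    spacing
        Voxel size ``(dx, dy, dz)`` in mm; all components positive.
    origin
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm coordinates."""
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(self.origin)


@dataclasses.dataclass
class BinaryMask:
    """A boolean ROI on the grid of a parent :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "PREDICTED"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}")

    shape = ImageVolume.shape
    voxel_volume_mm3 = ImageVolume.voxel_volume_mm3
    same_grid = ImageVolume.same_grid
    index_to_physical = ImageVolume.index_to_physical

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        """Foreground volume: voxel count times voxel volume."""
        return self.n_foreground * self.voxel_volume_mm3

    def foreground_points_mm(self) -> np.ndarray:
        """(N, 3) physical coordinates of foreground voxel centers."""
        idx = np.argwhere(self.voxels)
        return idx * np.array(self.spacing) + np.array(self.origin)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3D NIfTI-1 file as an :class:`ImageVolume`.

    Spacing is taken from the header zooms and the origin from the affine
    translation. Raises ``FileNotFoundError`` for missing files and
    ``ValueError`` for non-3D images.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return ImageVolume(data.astype(np.float32), spacing, origin)


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> str:
    """Write a volume to NIfTI-1. Returns the path written."""
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return str(path)


def read_mask(path: str | os.PathLike, label: str = "PREDICTED") -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.voxels > 0.5, vol.spacing, vol.origin, label=label)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> str:
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return str(path)


# ---------------------------------------------------------------------------
# Resampling, centroid, cropping


def resample_isotropic(
    vol: ImageVolume | BinaryMask,
    target_spacing: Sequence[float],
    interpolation: str = "linear",
) -> ImageVolume | BinaryMask:
    """Resample onto a grid with the given spacing, preserving physical extent.

    Intensities should use ``interpolation='linear'``; masks are resampled
    with ``'nearest'`` so they stay binary. The output grid keeps the input
    origin; the new voxel ``i`` samples physical position
    ``origin + i * target_spacing``.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be 3 positive values, got {target_spacing}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")

    old = np.array(vol.spacing)
    new = np.array(target_spacing)
    shape = np.array(vol.voxels.shape)
    # number of new voxels covering the same physical extent (at least 1)
    new_shape = np.maximum(1, np.round(shape * old / new).astype(int))

    grids = np.meshgrid(
        *[np.arange(n) * new[a] / old[a] for a, n in enumerate(new_shape)], indexing="ij"
    )
    coords = np.stack(grids)
    is_mask = isinstance(vol, BinaryMask)
    data = vol.voxels.astype(np.float32)
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(data, coords, order=order, mode="nearest")
    if is_mask:
        return BinaryMask(out > 0.5, target_spacing, vol.origin, label=vol.label)
    return ImageVolume(out, target_spacing, vol.origin)


def compute_centroid(mask: BinaryMask) -> tuple[float, float, float]:
    """Mean physical position (mm) of the foreground voxel centers."""
    if mask.n_foreground == 0:
        raise DegenerateInputError("centroid of an empty mask is undefined")
    idx = np.argwhere(mask.voxels).mean(axis=0)
    return tuple(mask.index_to_physical(idx))


def body_mask(vol: ImageVolume, threshold_hu: float = -300.0) -> BinaryMask:
    """Foreground of the body by HU threshold; fallback centroid source."""
    return BinaryMask(vol.voxels > threshold_hu, vol.spacing, vol.origin, label="BREAST")


def crop_around_centroid(
    vol: ImageVolume | BinaryMask,
    center_mm: Sequence[float],
    dims: Sequence[int],
) -> ImageVolume | BinaryMask:
    """Extract a window of exactly ``dims`` voxels centered on a physical point.

    Windows extending past the array are padded: intensities with air
    (−1024 HU), masks with background. The origin is updated so physical
    coordinates of retained voxels are unchanged.
    """
    dims = tuple(int(d) for d in dims)
    if any(d <= 0 for d in dims):
        raise ValueError(f"crop dims must be positive, got {dims}")
    is_mask = isinstance(vol, BinaryMask)
    center_idx = np.round(
        (np.asarray(center_mm, float) - np.array(vol.origin)) / np.array(vol.spacing)
    ).astype(int)
    start = center_idx - np.array(dims) // 2
    stop = start + np.array(dims)

    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(stop, np.array(vol.shape))
    if np.any(src_lo >= src_hi):
        raise ValueError("crop window lies entirely outside the volume")

    fill = False if is_mask else AIR_HU
    out = np.full(dims, fill, dtype=bool if is_mask else np.float32)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = vol.voxels[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    new_origin = tuple(np.array(vol.origin) + start * np.array(vol.spacing))
    if is_mask:
        return BinaryMask(out, vol.spacing, new_origin, label=vol.label)
    return ImageVolume(out, vol.spacing, new_origin)
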