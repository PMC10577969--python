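"""ROI intensity enhancement and network input conditioning.

The spatial prior is injected into the network inputs by brightening the
prior ROI and dimming everything else: voxel intensities inside the ROI
are multiplied by a large factor (25 by default) and those outside by a
small one (0.1 by default).

Multiplication only brightens on a nonnegative intensity scale, so the
pipeline first shifts CT values from HU to an offset scale
(HU + 1024, clamped at 0: air maps to 0) before enhancing; see
:func:`shift_to_nonnegative`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volumes import BinaryMask, GridMismatchError, ImageVolume


@dataclasses.dataclass(frozen=True)
class EnhancementParams:
    """Multipliers applied inside / outside the prior ROI."""

    inside_factor: float = 25.0
    outside_factor: float = 0.1

    def __post_init__(self):
        if not (self.inside_factor > self.outside_factor > 0):
            raise ValueError(
                f"need inside_factor > outside_factor > 0, got "
                f"({self.inside_factor}, {self.outside_factor})"
            )


def shift_to_nonnegative(vol: ImageVolume, offset: float = 1024.0) -> ImageVolume:
    """Map HU onto the nonnegative stored scale: max(HU + offset, 0)."""
    return ImageVolume(
        np.maximum(vol.voxels + offset, 0.0).astype(np.float32), vol.spacing, vol.origin
    )


def enhance_roi(
    intensities: ImageVolume,
    roi: BinaryMask,
    params: EnhancementParams | None = None,
) -> ImageVolume:
    """Multiply intensities by ``inside_factor`` in the ROI, ``outside_factor`` elsewhere.

    Exact elementwise arithmetic, no clipping: at equal raw value the
    enhanced inside/outside ratio is exactly ``inside_factor/outside_factor``
    (250 at the defaults). Input intensities must be nonnegative.
    """
    params = params or EnhancementParams()
    if not intensities.same_grid(roi):
        raise GridMismatchError("intensities and ROI are on different grids")
    if np.any(intensities.voxels < 0):
        raise ValueError("enhancement expects nonnegative intensities; shift HU first")
    out = np.where(
        roi.voxels,
        intensities.voxels * np.float32(params.inside_factor),
        intensities.voxels * np.float32(params.outside_factor),
    ).astype(np.float32)
    return ImageVolume(out, intensities.spacing, intensities.origin)


def normalize_for_network(vol: ImageVolume) -> ImageVolume:
    """Min–max scale a volume to [0, 1]; a constant volume maps to zeros."""
    v = vol.voxels.astype(np.float32)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return ImageVolume(out, vol.spacing, vol.origin)
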