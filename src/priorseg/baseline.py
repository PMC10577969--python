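"""Traditional gray-level-threshold comparator.

The classical alternative to learned segmentation: every voxel whose CT
value lies strictly above a threshold (40 HU by default) and inside the
breast region is labeled CTV-TB. Operates on raw HU, not on the shifted
scale used for network enhancement.
"""

from __future__ import annotations

import dataclasses

from .volumes import BinaryMask, GridMismatchError, ImageVolume


@dataclasses.dataclass
class ThresholdParams:
    """Threshold (HU) and the breast mask restricting the search region."""

    restrict_to: BinaryMask
    hu_threshold: float = 40.0

    def __post_init__(self):
        if self.restrict_to.n_foreground == 0:
            raise ValueError("restrict_to mask is empty")


def threshold_segment(vol: ImageVolume, params: ThresholdParams) -> BinaryMask:
    """Voxels with HU strictly above the threshold, inside the breast region."""
    if not vol.same_grid(params.restrict_to):
        raise GridMismatchError("volume and breast mask are on different grids")
    fg = (vol.voxels > params.hu_threshold) & params.restrict_to.voxels
    return BinaryMask(fg, vol.spacing, vol.origin, label="PREDICTED")
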