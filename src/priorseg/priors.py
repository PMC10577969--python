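"""Construction and calibration of the prior ROIs.

The spatial prior for tumor-bed segmentation is built from the primary
tumor (PT) contour on the preoperative scan:

* EV      — excision volume, PT expanded by a calibrated margin (2 cm by
            default, selected so the expanded volume best matches the
            pathology report's excised-tissue volume),
* EV_1cm  — EV expanded by a further 1 cm, mirroring the 1 cm margin that
            turns the tumor bed (TB) into its clinical target volume
            (CTV-TB) on the postoperative scan.

Margins are physical (mm) and anisotropic-spacing aware: a voxel belongs to
the expanded mask iff its center lies within the margin (Euclidean distance,
inclusive) of some foreground voxel center.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, DegenerateInputError


@dataclasses.dataclass(frozen=True)
class PathologyRecord:
    """Three maximum diameters (mm) of the excised specimen."""

    diameters: tuple[float, float, float]

    def __post_init__(self):
        if len(self.diameters) != 3 or any(d <= 0 for d in self.diameters):
            raise ValueError(f"need 3 positive diameters, got {self.diameters}")


@dataclasses.dataclass(frozen=True)
class MarginSpec:
    """An inclusive isotropic physical margin in mm."""

    margin_mm: float

    def __post_init__(self):
        if self.margin_mm < 0:
            raise ValueError(f"margin must be >= 0, got {self.margin_mm}")


def expand_margin(mask: BinaryMask, margin: MarginSpec | float) -> BinaryMask:
    """Expand a mask by a physical margin (mm).

    Implemented with a Euclidean distance transform weighted by the voxel
    spacing, so a 5 mm margin on (1, 1, 5) mm voxels grows ~5 voxels
    in-plane but at most one slice axially. The boundary rule is inclusive
    (distance <= margin is inside) and margin 0 is the identity.
    """
    margin_mm = margin.margin_mm if isinstance(margin, MarginSpec) else float(margin)
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    if mask.n_foreground == 0:
        raise DegenerateInputError("cannot expand an empty mask")
    if margin_mm == 0:
        return BinaryMask(mask.voxels.copy(), mask.spacing, mask.origin, label=mask.label)
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)
    return BinaryMask(dist <= margin_mm, mask.spacing, mask.origin, label=mask.label)


def pathological_volume(rec: PathologyRecord) -> float:
    """Excised-tissue volume (mm^3) from the three maximum diameters.

    Uses the ellipsoid model PV = (pi/6) d1 d2 d3, the standard clinical
    approximation for a specimen measured by its three maximum diameters.
    """
    d1, d2, d3 = rec.diameters
    return float(np.pi / 6.0 * d1 * d2 * d3)


def calibrate_margin(
    pt: BinaryMask,
    rec: PathologyRecord,
    candidates: Sequence[float] = (10.0, 20.0, 30.0),
) -> float:
    """Select the PT->EV margin whose expanded volume best matches PV.

    Evaluates each candidate margin (mm), expands PT by it, and returns the
    candidate minimizing ``|volume(expanded PT) - PV|``. Ties break to the
    smaller margin (the conservative excision estimate).
    """
    candidates = [float(c) for c in candidates]
    if not candidates:
        raise ValueError("candidate margin list is empty")
    if pt.n_foreground == 0:
        raise DegenerateInputError("PT mask is empty")
    pv = pathological_volume(rec)
    best, best_gap = None, np.inf
    for m in sorted(candidates):
        gap = abs(expand_margin(pt, m).volume_mm3 - pv)
        if gap < best_gap:
            best, best_gap = m, gap
    return best


def build_prior_rois(
    pt: BinaryMask, margin_ev: float, margin_ctv: float = 10.0
) -> tuple[BinaryMask, BinaryMask]:
    """Build (EV, EV_1cm) from the primary tumor contour.

    EV = PT expanded by ``margin_ev``; EV_1cm = EV expanded by
    ``margin_ctv`` (1 cm by default). Nesting PT ⊆ EV ⊆ EV_1cm holds by
    construction.
    """
    ev = expand_margin(pt, margin_ev)
    ev = BinaryMask(ev.voxels, ev.spacing, ev.origin, label="EV")
    ev_1cm = expand_margin(ev, margin_ctv)
    ev_1cm = BinaryMask(ev_1cm.voxels, ev_1cm.spacing, ev_1cm.origin, label="EV_1cm")
    return ev, ev_1cm
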