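"""Synthetic paired pre-/post-operative CT phantoms with full ground truth.

Each case emulates the clinical material the pipeline was designed for:

* a preoperative scan of a soft-tissue breast (HU ≈ 0 with smooth
  fat/gland texture) containing a denser primary tumor,
* a postoperative scan in which the tumor has been excised: the cavity is
  filled with seroma-like intensities whose mean differs from surrounding
  tissue by well under 30 HU (the low-contrast regime that makes tumor-bed
  delineation hard), with at least five high-density surgical-clip markers
  on the cavity rim,
* a smooth random inter-scan deformation with known ground truth
  (``true_dvf``) relating the two frames,
* a pathology record whose three maximum diameters encode an excision of
  the tumor plus a 2 cm surgical margin, so margin calibration against the
  pathological volume selects 2 cm.

Everything is deterministic given the seed. The default grid is
64×64×16 voxels at (2, 2, 5) mm — a 128×128×80 mm field of view with the
same in-plane/axial aspect as a clinical breast crop, small enough for
CPU-scale experiments while leaving room for the fixed 2 cm + 1 cm prior
margins to stay spatially informative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .priors import PathologyRecord, expand_margin
from .registration import DeformationField, warp_mask, warp_volume
from .volumes import AIR_HU, BinaryMask, ImageVolume


@dataclasses.dataclass
class PhantomParams:
    """Geometry, intensity and deformation settings for one phantom case."""

    grid: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)
    breast_radius_mm: tuple[float, float] = (38.0, 46.0)  # in-plane semi-axes
    breast_z_radius_mm: tuple[float, float] = (26.0, 32.0)
    tumor_radius_mm: tuple[float, float] = (8.0, 14.0)
    tumor_hu_offset: float = 60.0
    seroma_hu: float = 20.0
    cavity_margin_mm: float = 3.0
    n_clips: int = 6
    clip_hu: float = 2000.0
    clip_radius_mm: float = 2.0
    deformation_amplitude_mm: float = 8.0
    n_deformation_bumps: int = 3
    noise_sd_hu: float = 8.0
    texture_sd_hu: float = 18.0
    texture_sigma_mm: float = 6.0
    excision_margin_mm: float = 20.0
    ctv_margin_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clips < 5:
            raise ValueError("at least 5 surgical clips are required")
        if self.tumor_radius_mm[1] + self.cavity_margin_mm >= self.breast_radius_mm[0]:
            raise ValueError("tumor does not fit inside the breast")
        if self.deformation_amplitude_mm >= min(self.breast_radius_mm) / 4:
            raise ValueError("deformation amplitude must stay below breast radius / 4")


@dataclasses.dataclass
class PhantomCase:
    """One synthetic patient: volumes, ground-truth ROIs, true deformation."""

    case_id: str
    preop: ImageVolume
    postop: ImageVolume
    pt: BinaryMask          # primary tumor, pre-op frame
    tb: BinaryMask          # tumor bed, post-op frame
    ctv_tb: BinaryMask      # tb expanded by the CTV margin, post-op frame
    breast_pre: BinaryMask
    breast_post: BinaryMask
    clips: BinaryMask       # clip marker voxels, post-op frame
    true_dvf: DeformationField
    pathology: PathologyRecord
    seed: int = 0

    @property
    def breast(self) -> BinaryMask:
        """Breast region in the frame where segmentation happens (post-op)."""
        return self.breast_post


def _ellipsoid(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    out = np.zeros(shape, dtype=np.float64)
    for ax in range(3):
        out += ((idx[ax] * spacing[ax] - center_mm[ax]) / semi_axes_mm[ax]) ** 2
    return out <= 1.0


def _smooth_texture(rng, shape, spacing, sigma_mm, sd_hu) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, shape)
    sigma_vox = [sigma_mm / s for s in spacing]
    tex = ndimage.gaussian_filter(noise, sigma_vox)
    tex *= sd_hu / max(tex.std(), 1e-12)
    return tex


def _random_smooth_field(rng, shape, spacing, params) -> DeformationField:
    """Sum of random Gaussian displacement bumps, scaled to the target amplitude."""
    extent = np.array(shape) * np.array(spacing)
    idx = np.indices(shape, dtype=np.float64)
    phys = [idx[ax] * spacing[ax] for ax in range(3)]
    u = np.zeros(shape + (3,), dtype=np.float64)
    for _ in range(params.n_deformation_bumps):
        center = rng.uniform(0.25, 0.75, 3) * extent
        sigma = rng.uniform(18.0, 30.0)
        direction = rng.normal(0.0, 1.0, 3)
        direction[2] *= 0.5  # inter-scan posture change is mostly in-plane
        direction /= np.linalg.norm(direction)
        r2 = sum((phys[ax] - center[ax]) ** 2 for ax in range(3))
        bump = np.exp(-r2 / (2.0 * sigma ** 2))
        u += bump[..., None] * direction
    mag = np.sqrt((u ** 2).sum(-1)).max()
    u *= params.deformation_amplitude_mm / max(mag, 1e-12)
    return DeformationField(u.astype(np.float32), tuple(spacing))


def _clip_mask_on_rim(tb: BinaryMask, params: PhantomParams) -> np.ndarray:
    """Paint small high-density balls spread around the tumor-bed rim.

    Clip centers are rim voxels picked at evenly spaced azimuth angles
    around the cavity center, so markers surround the cavity the way
    surgical clips outline a lumpectomy bed.
    """
    rim = tb.voxels & ~ndimage.binary_erosion(tb.voxels)
    rim_idx = np.argwhere(rim)
    center = rim_idx.mean(0)
    ang = np.arctan2(
        (rim_idx[:, 1] - center[1]) * tb.spacing[1],
        (rim_idx[:, 0] - center[0]) * tb.spacing[0],
    )
    order = np.argsort(ang, kind="stable")
    picks = order[np.linspace(0, len(order) - 1, params.n_clips, dtype=int)]
    clip_mask = np.zeros(tb.shape, dtype=bool)
    idx = np.indices(tb.shape, dtype=np.float64)
    for p in rim_idx[picks]:
        r2 = sum(((idx[ax] - p[ax]) * tb.spacing[ax]) ** 2 for ax in range(3))
        clip_mask |= r2 <= params.clip_radius_mm ** 2
    return clip_mask


def generate_case(params: PhantomParams, case_id: str = "case000") -> PhantomCase:
    """Generate one deterministic phantom case from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    shape, spacing = tuple(params.grid), tuple(params.spacing)
    extent = np.array(shape) * np.array(spacing)

    # breast ellipsoid
    br_inplane = rng.uniform(*params.breast_radius_mm, 2)
    br_z = rng.uniform(*params.breast_z_radius_mm)
    br_axes = (br_inplane[0], br_inplane[1], br_z)
    br_center = extent / 2 + np.concatenate([rng.uniform(-4, 4, 2), rng.uniform(-2, 2, 1)])
    breast_vox = _ellipsoid(shape, spacing, br_center, br_axes)
    breast_pre = BinaryMask(breast_vox, spacing, label="BREAST")

    # tumor ellipsoid inside the breast
    t_axes = rng.uniform(*params.tumor_radius_mm, 3)
    for _ in range(100):
        offset = np.concatenate([rng.uniform(-12, 12, 2), rng.uniform(-8, 8, 1)])
        t_center = br_center + offset
        # conservative containment: cavity must stay inside the breast
        frac = sum(
            ((abs(offset[ax]) + t_axes[ax] + params.cavity_margin_mm) / br_axes[ax]) ** 2
            for ax in range(3)
        )
        if frac <= 0.9:
            break
    else:
        raise ValueError("could not place the tumor inside the breast")
    pt = BinaryMask(_ellipsoid(shape, spacing, t_center, t_axes), spacing, label="PT")

    # intensities: soft tissue ~0 HU with smooth texture, air background
    tex = _smooth_texture(rng, shape, spacing, params.texture_sigma_mm, params.texture_sd_hu)
    tissue = np.where(breast_vox, tex, AIR_HU)
    pre_clean = tissue + params.tumor_hu_offset * pt.voxels
    preop = ImageVolume(
        (pre_clean + rng.normal(0.0, params.noise_sd_hu, shape)).astype(np.float32),
        spacing,
    )

    # post-op frame before deformation: tumor replaced by a seroma cavity
    cavity = expand_margin(pt, params.cavity_margin_mm)
    post_clean = np.where(cavity.voxels, params.seroma_hu + 0.3 * tex, tissue)

    # smooth inter-scan deformation with known ground truth
    dvf = _random_smooth_field(rng, shape, spacing, params)
    post_warped = warp_volume(ImageVolume(post_clean.astype(np.float32), spacing), dvf)
    tb = warp_mask(BinaryMask(cavity.voxels, spacing, label="TB"), dvf)

    # clips are implanted in the post-op anatomy: paint them crisply on the
    # deformed cavity rim rather than dragging metal HU through the warp
    clip_vox = _clip_mask_on_rim(tb, params)
    post_voxels = np.where(clip_vox, params.clip_hu, post_warped.voxels)
    postop = ImageVolume(
        (post_voxels + rng.normal(0.0, params.noise_sd_hu, shape)).astype(np.float32),
        spacing,
    )

    ctv_tb = expand_margin(tb, params.ctv_margin_mm)
    ctv_tb = BinaryMask(ctv_tb.voxels, spacing, label="CTV-TB")
    breast_post = warp_mask(breast_pre, dvf)
    clips = BinaryMask(clip_vox, spacing, label="PREDICTED")

    diameters = tuple(2.0 * t_axes + 2.0 * params.excision_margin_mm)
    return PhantomCase(
        case_id=case_id,
        preop=preop,
        postop=postop,
        pt=pt,
        tb=tb,
        ctv_tb=ctv_tb,
        breast_pre=breast_pre,
        breast_post=breast_post,
        clips=clips,
        true_dvf=dvf,
        pathology=PathologyRecord(diameters),
        seed=params.seed,
    )


def tb_contrast_hu(case: PhantomCase) -> float:
    """Mean HU difference between the tumor bed and surrounding breast tissue.

    Clip voxels (metal) are excluded from the tumor-bed side and the
    tissue side is taken from the eroded breast outside the CTV, so the
    number reflects soft-tissue contrast only. Small by construction:
    the low-contrast regime is what makes this segmentation problem hard.
    """
    clip_dil = ndimage.binary_dilation(case.clips.voxels, np.ones((3, 3, 3)))
    tb_core = case.tb.voxels & ~clip_dil
    tissue = (
        ndimage.binary_erosion(case.breast_post.voxels, iterations=2)
        & ~case.ctv_tb.voxels
    )
    if not tb_core.any() or not tissue.any():
        raise ValueError("degenerate phantom: no clip-free tumor-bed voxels")
    return float(
        case.postop.voxels[tb_core].mean() - case.postop.voxels[tissue].mean()
    )


def generate_cohort(n: int, params: PhantomParams | None = None) -> list[PhantomCase]:
    """Generate ``n`` cases with per-case seeds derived from ``params.seed``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    params = params or PhantomParams()
    cases = []
    for i in range(n):
        case_params = dataclasses.replace(params, seed=params.seed)
        # derive a distinct, deterministic stream per case
        rng_seed = np.random.SeedSequence([params.seed, i]).generate_state(1)[0] % (2 ** 31)
        case_params = dataclasses.replace(params, seed=int(rng_seed))
        cases.append(generate_case(case_params, case_id=f"case{i:03d}"))
    return cases
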