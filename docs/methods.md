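# Methods

`priorseg` implements prior-information-guided auto-segmentation of the
clinical target volume of the tumor bed (CTV-TB) on postoperative breast
CT. This note documents the model, the parameters that matter, the
synthetic data the package is validated on, and the numerical choices
made where the design was open.

## The segmentation problem

After breast-conserving surgery, radiotherapy boost planning requires the
tumor bed (TB) — the cavity left by the excised tumor — plus a 1 cm
safety margin (CTV-TB) to be contoured on the planning CT. The cavity has
almost no soft-tissue contrast against surrounding breast tissue (tens of
HU at most), so pure intensity-based segmentation fails. The preoperative
scan, however, shows the tumor clearly, and the excised volume sits where
the tumor was. The pipeline therefore builds a *spatial prior* from the
preoperative tumor contour and injects it into a learned segmentation
model:

1. **Prior construction.** The primary tumor contour (PT) is expanded by
   a margin calibrated against the pathology report: the excision volume
   EV is PT + *m*, where *m* ∈ {1, 2, 3} cm is chosen to minimize
   |vol(PT + m) − PV| and PV = (π/6)·d₁d₂d₃ is the ellipsoid estimate of
   the excised specimen from its three maximum diameters. With
   realistically sized excisions the calibration selects 2 cm. A further
   1 cm expansion (mirroring the TB → CTV-TB margin) gives the prior ROI
   EV_1cm.
2. **Prior transfer.** Deformable registration of the preoperative
   (moving) to the postoperative (fixed) CT yields a dense deformation
   vector field (DVF); warping EV_1cm through it produces T-EV_1cm, the
   prior in the postoperative frame.
3. **Enhancement.** Both scans are shifted to a nonnegative scale
   (HU + 1024, clamped at 0) and multiplied by 25 inside their prior ROI
   (EV_1cm on the pre-op scan, T-EV_1cm on the post-op scan) and by 0.1
   outside, then min–max normalized. At equal raw intensity the
   inside/outside ratio is exactly 250: the prior is encoded in
   intensity.
4. **Segmentation.** A two-channel 3D U-Net maps (enhanced pre-op,
   enhanced post-op) to a per-voxel CTV-TB probability; thresholding at
   0.5 and keeping the largest 26-connected component gives the
   predicted mask.
5. **Evaluation.** Dice similarity DSC = 2|A∩B|/(|A|+|B|) and the
   symmetric Hausdorff distance HD = max(h(A,B), h(B,A)),
   h(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖, computed over all foreground
   voxel centers in physical mm. Method arms are compared case-paired: a
   Shapiro–Wilk test on the paired differences (α = 0.05) selects the
   paired t-test (normal) or the Wilcoxon signed-rank test (otherwise).

Two comparison arms accompany the prior-guided model: the same network
with the *raw* postoperative channel (enhanced pre-op + unenhanced
post-op — the prior only in the preoperative frame), and a traditional
gray-level threshold (voxels strictly above 40 HU inside the breast).

## Coordinate and data conventions

Volumes are 3D arrays indexed `[i, j, k]` (k the slice axis) with
physical position `origin + index × spacing` in mm; voxel indices are
0-based. I/O is NIfTI-1; masks are uint8 {0, 1}; the DVF is stored as a
4D NIfTI of (ux, uy, uz) components in mm on the fixed grid. Margins use
a spacing-weighted Euclidean distance transform with an inclusive
boundary (distance ≤ margin), so anisotropic voxels are handled
correctly: a 5 mm margin on (1, 1, 5) mm voxels adds ~5 voxels in-plane
but at most one slice axially. Crops pad with −1024 HU (air) for images
and background for masks so requested dimensions are always honored.

## Registration

Same-modality CT pairs are aligned with multi-resolution symmetric-forces
demons under the SSD criterion (SimpleITK's demons filter inside an
in-repo image pyramid), with Gaussian smoothing of the displacement
field. Defaults: 3 pyramid levels (in-plane shrink halves per level; the
thick-slice axis shrinks less and never below 8 slices), 40 iterations
per level, field smoothing σ = 2 mm, maximum update step 1 voxel. The
optimization has no random component: identical inputs give bit-identical
fields. The DVF follows the *pull* convention — the warped image samples
the moving image at x + u(x) — which is the direction needed to carry a
preoperative contour into the postoperative frame. Masks are warped with
linear interpolation re-binarized at 0.5.

On phantoms with known smooth deformations of ≤ 6 mm amplitude the
registration recovers pure translations to well under 1 mm mean error and
reproduces the ground-truth prior transfer with DSC ≈ 0.94; it is *not* a
reconstruction of any particular clinical registration package and makes
no claims about large or non-diffeomorphic clinical deformations.

## Network and training

The U-Net backbone is conv(3³) → instance-norm → leaky-ReLU(0.1) blocks
with 3D max-pooling on the way down, nearest-neighbor upsampling and skip
concatenation on the way up, and a 1×1×1 sigmoid head. Instance
normalization is load-bearing: with a pure soft-Dice loss
(1 − (2Σpt + ε)/(Σp + Σt + ε), ε = 1) an unnormalized network whose head
saturates has vanishing gradients and can collapse irrecoverably to an
empty prediction; keeping activations O(1) removes that failure mode.
Weights are He-scaled normal draws from a seeded generator. The entire
backend is NumPy (im2col convolutions backed by BLAS matrix products), so
training is single-threaded, CPU-friendly and bit-reproducible.

The optimization schedule follows the clinical study: Adam, batch size 4,
weight decay 3e-5 (L2, applied to convolution weights only), learning
rate multiplied by 0.95 once per epoch, at most 50 epochs, validation
loss monitored every 20 iterations (monitoring only — no early
stopping). The clinical initial rate of 5e-4 is appropriate for tens of
thousands of optimization steps; the desk-scale experiment (below) has
only ~30 steps, so its default configuration (`desk_train_config`) uses
0.1 with a depth-2, base-4-channel network on the 64×64×16 grid —
settings chosen so the small model converges within the steps available.
Binarization threshold 0.5 and the largest-component post-filter reflect
that a single tumor bed is anatomically expected.

## The phantom cohort: what it emulates and what it does not

Each synthetic case contains: a breast ellipsoid of soft tissue
(HU ≈ 0 plus smooth σ = 6 mm texture, sd 18 HU) in air; a denser
(+60 HU) tumor ellipsoid with semi-axes 8–14 mm (T1–T2-like); a
postoperative frame where the tumor plus a 3 mm surgical margin is
replaced by seroma-like intensities (20 HU — within ±30 HU of
surrounding tissue, the low-contrast regime that motivates the method);
six 2 mm-radius clips (2000 HU) spread around the deformed cavity rim;
and a smooth inter-scan deformation (sum of 3 random Gaussian bumps,
σ 18–30 mm, peak 8 mm, mostly in-plane) with known ground truth.
Pathology diameters are tumor diameters + 2 × 20 mm, encoding an
excision of the tumor plus a 2 cm surgical margin, so margin calibration
selects 2 cm for every case. The grid is 64×64×16 voxels at
(2, 2, 5) mm: a 128×128×80 mm field of view with the same
in-plane/axial aspect as a clinical breast crop, but small enough that
the fixed 2 cm + 1 cm prior margins remain spatially informative (the
prior covers ~20 % of the volume rather than all of it) and that CPU
training is feasible. Everything is deterministic given the master seed;
per-case seeds derive from it.

Not emulated: ribs, lung, chest wall, metal streak artifacts (clips are
clean high-HU blobs), non-elastic or very large inter-scan deformation,
seroma heterogeneity, and anatomy-aware trimming of margins at the skin
(margins are purely geometric; the clinical practice of trimming the CTV
to the body contour is out of scope). Passing tests on phantoms
demonstrates that the pipeline's machinery — prior construction,
transfer, enhancement, learning, evaluation — behaves correctly and that
the prior helps under controlled conditions; it does not certify clinical
accuracy on real scans.

## The desk-scale experiment

`run_experiment` performs k-fold cross-validation (default: 24 cases,
2 folds, 8 epochs) over the three arms, aggregates per-case DSC/HD as
mean ± sample sd, and runs the gated paired comparisons. An empty
prediction scores DSC 0 against a non-empty reference but has no defined
Hausdorff distance; such cases are recorded as NaN and excluded from HD
aggregation and pairing. At the default master seed the arms order as the
method predicts: prior-guided > no-prior > threshold on DSC, reversed on
HD. The margin between the two learning arms is structurally thinner here
than in a clinical setting: the phantom's inter-scan deformation is
bounded at 8 mm (a quarter of the breast radius, to keep the synthetic
warp invertible), so the *preoperative* enhanced channel — which both
arms share — already localizes the target fairly well, and on individual
seeds the two arms can come close or occasionally tie. The threshold
baseline, with no spatial information, is far behind throughout.

## Numerical choices and edge cases

- Soft-Dice smoothing ε = 1 (voxel-count scale); loss and gradients are
  computed in float64, network arithmetic in float32.
- Sigmoid outputs are clamped to (1e-12, 1 − 1e-12), keeping the range
  contract strict without affecting training.
- DSC of two empty masks is undefined and raises; Hausdorff of any empty
  mask raises. `paired_compare` refuses all-zero difference vectors
  (degenerate flag) rather than fabricating a p-value.
- Margin expansion of an empty mask raises (degenerate input).
- Calibration ties break to the smaller margin (conservative excision
  estimate).
- Thresholding is strictly `> 40 HU`, on raw HU, never on the shifted
  scale used for enhancement.
- `make_folds` shuffles with the seed and deals round-robin: fold sizes
  differ by at most one; 110 cases with k = 5 give five folds of 22.
- Voxelized margin composition expand(expand(X, a), b) agrees with
  expand(X, a + b) only up to one voxel of discretization (the
  intermediate voxelization can round either way); tests assert the
  mismatch is confined to that shell rather than a strict containment.

## Known limitations

The NumPy backend is adequate for the desk-scale grids it ships with;
paper-scale grids (256×256×32) train slowly on one CPU. The demons
registration assumes same-modality intensities and modest smooth
deformations. The phantom's difficulty is a lower bound on clinical
difficulty: real seroma clarity, artifact load, and deformation are all
worse. Reported clinical-scale accuracies are not reproducible from this
package and are not claimed by it.
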