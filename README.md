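# priorseg

Prior-information-guided auto-segmentation of the clinical target volume
of the tumor bed (CTV-TB) on postoperative breast CT.

## The problem

After breast-conserving surgery, boost radiotherapy targets the tumor
bed — the cavity where the excised tumor sat — plus a 1 cm margin
(CTV-TB). On planning CT the cavity is nearly isodense with surrounding
breast tissue, so contouring it is hard for humans and nearly hopeless
for plain intensity-based methods. The tumor, however, was clearly
visible on the *preoperative* scan, and the cavity is where the tumor
was. `priorseg` exploits that: it builds a spatial prior from the
preoperative tumor contour, carries it into the postoperative frame by
deformable image registration (DIR), encodes it into the image
intensities, and lets a two-channel 3D U-Net do the rest.

The pipeline, per case:

1. **Prior construction** — expand the primary tumor (PT) by a margin
   calibrated against the pathology report: EV = PT + *m*, with *m*
   chosen from {1, 2, 3} cm to match the pathological volume
   PV = (π/6)·d₁d₂d₃ (the calibration selects 2 cm); EV_1cm = EV + 1 cm
   is the prior ROI.
2. **Prior transfer** — register pre→post CT (multi-resolution demons,
   SSD), obtain the deformation vector field (DVF), warp EV_1cm to
   T-EV_1cm on the postoperative grid.
3. **Enhancement** — on a nonnegative intensity scale, multiply voxels
   inside the prior ROI by 25 and outside by 0.1 (inside/outside ratio
   exactly 250 at equal raw value).
4. **Segmentation** — a 3D U-Net with two input channels (enhanced
   pre-op, enhanced post-op) and a sigmoid voxel-probability output,
   trained with soft-Dice loss (Adam, batch 4, weight decay 3e-5,
   per-epoch learning-rate drop 0.95); threshold 0.5, keep the largest
   connected component.
5. **Evaluation** — Dice similarity coefficient
   DSC = 2|A∩B|/(|A|+|B|) and Hausdorff distance
   HD = max(h(A,B), h(B,A)), h(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖ (mm),
   with Shapiro–Wilk-gated paired t / Wilcoxon comparisons between
   method arms.

Clinical CT pairs are private data; the package ships a **phantom
module** that generates fully ground-truthed synthetic pre/post CT pairs
(soft-tissue breast, low-contrast seroma cavity, ≥ 5 surgical clips,
known smooth inter-scan deformation), so every stage — and the full
three-arm comparison against a no-prior network and a 40 HU threshold
baseline — runs end-to-end on one CPU. See `docs/methods.md` for the
model details and the phantom's fidelity limits.

## Worked example

```bash
python examples/03_register_and_transfer_prior.py
```

```
mean displacement inside the breast: estimated 3.4 mm, true 3.1 mm
SSD before registration: 1.1e+09
SSD after registration:  2.07e+08  (81% reduction)
T-EV_1cm vs ground-truth transfer: DSC = 0.952
T-EV_1cm vs reference CTV-TB:      DSC = 0.293
```

The registration recovers the synthetic inter-scan deformation almost
exactly (DSC 0.952 against the ground-truth warp of the prior), and the
transferred prior overlaps the true CTV-TB loosely (DSC ≈ 0.3) — it
marks *where to look*, not the answer. The network sharpens it:

```bash
python examples/06_three_arm_experiment.py
```

```
arm             DSC (mean±sd)       HD mm (mean±sd)
with_prior      0.718 ± 0.076       11.32 ± 2.51
without_prior   0.673 ± 0.077       11.91 ± 2.76
baseline        0.041 ± 0.013       22.12 ± 3.55

T-EV_1cm prior vs reference CTV-TB: DSC 0.289 ± 0.021

paired comparisons (per-case):
  dsc:with_prior_vs_without_prior: paired-t, p = 0.0033 *
  dsc:with_prior_vs_baseline: paired-t, p = 2.9e-23 *
```

(24 phantom cases, 2-fold cross-validation, ~3 min on one CPU; numbers
from master seed 0.) The prior-guided network beats the same network
without the postoperative prior, and both leave the intensity-threshold
baseline far behind — higher Dice, lower Hausdorff distance — which is
exactly the ordering the prior-guidance idea predicts. Other examples
cover phantom generation, margin calibration, ROI enhancement, and
single-case training/prediction with PNG contour overlays.

A thin CLI mirrors the library (`priorseg phantom | preprocess | priors |
register | warp | enhance | baseline | evaluate | experiment | overlay`);
run `priorseg --help`.

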