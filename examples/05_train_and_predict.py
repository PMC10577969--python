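"""Train the two-channel 3D U-Net on a handful of phantoms and predict.

A deliberately small demonstration: nine training cases, one held-out
case, a few epochs. The full cross-validated comparison lives in
``06_three_arm_experiment.py``.
"""

import numpy as np

from priorseg import (
    PhantomParams,
    PipelineConfig,
    dsc,
    export_overlay,
    generate_cohort,
    hausdorff,
    predict,
    prepare_case,
    train,
)
from priorseg.pipeline import desk_train_config, network_input
from priorseg.unet_model import build_unet

config = PipelineConfig(train=desk_train_config())
cohort = generate_cohort(10, PhantomParams(seed=3))
held_out, training = cohort[0], cohort[1:]

print("preparing cases (registration + prior transfer + enhancement)...")
inputs = {c.case_id: prepare_case(c, config) for c in cohort}

data = [
    (network_input(inputs[c.case_id], "with_prior"), c.ctv_tb.voxels.astype(np.float32))
    for c in training
]
net = build_unet(config.train)
net, history = train(net, data, config.train)
print("per-epoch mean Dice loss:", [round(x, 3) for x in history["epoch_loss"]])

ci = inputs[held_out.case_id]
mask = predict(net, ci.pre_enhanced, ci.post_enhanced)
print(f"held-out case {held_out.case_id}:")
print(f"  predicted volume {mask.volume_mm3:.0f} mm^3, reference {held_out.ctv_tb.volume_mm3:.0f} mm^3")
print(f"  DSC = {dsc(mask, held_out.ctv_tb):.3f}")
if mask.n_foreground:
    print(f"  HD  = {hausdorff(mask, held_out.ctv_tb):.1f} mm")

paths = export_overlay(held_out.postop, mask, held_out.ctv_tb, "prediction")
print("overlays (predicted contour white, reference black):", ", ".join(paths))
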