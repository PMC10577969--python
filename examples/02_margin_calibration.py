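"""Calibrate the tumor-to-excision margin against the pathology report.

The excision volume (EV) is the primary tumor plus a margin. The margin is
chosen so the expanded contour's volume best matches the pathological
volume PV = (pi/6) d1 d2 d3 computed from the three maximum specimen
diameters. EV plus a further 1 cm gives the prior ROI EV_1cm.
"""

from priorseg import (
    PhantomParams,
    build_prior_rois,
    calibrate_margin,
    expand_margin,
    generate_case,
    pathological_volume,
)

case = generate_case(PhantomParams(seed=7))
pv = pathological_volume(case.pathology)
print(f"pathological volume PV = {pv:.0f} mm^3")

for m in (10.0, 20.0, 30.0):
    vol = expand_margin(case.pt, m).volume_mm3
    print(f"  PT + {m:.0f} mm margin -> {vol:9.0f} mm^3  (|gap| = {abs(vol - pv):9.0f})")

margin = calibrate_margin(case.pt, case.pathology, [10.0, 20.0, 30.0])
print(f"calibrated margin: {margin:.0f} mm  (the 2 cm margin of the clinical workflow)")

ev, ev_1cm = build_prior_rois(case.pt, margin)
print(f"EV volume:     {ev.volume_mm3:9.0f} mm^3")
print(f"EV_1cm volume: {ev_1cm.volume_mm3:9.0f} mm^3 (the preoperative prior ROI)")
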