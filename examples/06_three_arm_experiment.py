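"""Cross-validated three-arm comparison on a phantom cohort.

Reproduces the qualitative result of prior-guided segmentation at desk
scale: the network that sees the transferred, enhanced prior outperforms
the same network without the postoperative prior, and both beat the
traditional 40 HU gray-level threshold — higher DSC and lower Hausdorff
distance. Runs in a few minutes on one CPU; shrink --n or epochs for a
quicker look.
"""

import time

from priorseg import PipelineConfig, run_experiment

config = PipelineConfig(master_seed=0, n_cases=24, k_folds=2)
t0 = time.time()
report = run_experiment(None, config)
print(f"experiment finished in {time.time() - t0:.0f}s\n")

s = report.summary()
print(f"{'arm':<16}{'DSC (mean±sd)':<20}{'HD mm (mean±sd)':<20}")
for arm in ("with_prior", "without_prior", "baseline"):
    d = s[f"{arm}.dsc"]
    h = s[f"{arm}.hd_mm"]
    print(f"{arm:<16}{d['mean']:.3f} ± {d['sd']:.3f}      {h['mean']:6.2f} ± {h['sd']:.2f}")
p = s["prior.dsc"]
print(f"\nT-EV_1cm prior vs reference CTV-TB: DSC {p['mean']:.3f} ± {p['sd']:.3f}")

print("\npaired comparisons (per-case):")
for label, cmp in report.comparisons.items():
    print(f"  {label}: {cmp.test_name}, p = {cmp.p_value:.2g}"
          f"{' *' if cmp.significant else ''}")
print("\nThe expected ordering — prior-guided > no-prior > threshold on DSC,")
print("reversed on HD — mirrors the clinical finding that a transferred")
print("tumor-location prior substantially improves CTV-TB auto-segmentation.")
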