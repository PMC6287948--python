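"""The headline experiment: residual contrast biases repeat injections.

Simulates the full study design — two injections ~32 min apart on each of
two consecutive days, contrast eliminated with a 1.6 h serum half-life —
with TRUE perfusion held fixed across all four acquisitions.  Roughly 79%
of the first dose's steady-state concentration still circulates at the
second injection; combined with the saturating (non-linear) MRI signal it
dampens the measured AIF more than the dilute tissue signal, inflating
the estimated PBV and PBF at injection 2 even though nothing physiological
changed.  After 24 h less than 0.005% remains, so elimination kinetics
alone produce no day effect.
"""

import numpy as np

from lungdce import (
    ExperimentDesign, carryover_schedule, mechanism_report, run_experiment,
    wilcoxon_signed_rank,
)

design = ExperimentDesign(n_subjects=10, seed=0)
sched = carryover_schedule(design)
print("scheduled residual fraction (of one dose's steady state):")
for (day, inj), r in sorted(sched.items()):
    print(f"  day {day}, injection {inj}: {r:.3g}")

result = run_experiment(design)
pbv1, pbv2 = result.study.pairs("injection", "PBV", regions="whole")
aif1, aif2 = result.study.pairs("injection", "AIF", regions="whole")
print(f"\nwhole-lung PBV: injection 1 {pbv1.mean():.2f}, "
      f"injection 2 {pbv2.mean():.2f} ml/100ml "
      f"({100 * (pbv2.mean() / pbv1.mean() - 1):+.1f}%)")
print(f"subjects with inflated PBV at injection 2: "
      f"{int(np.sum(pbv2 > pbv1))}/{len(pbv1)} subject-days")
print(f"measured AIF integral change: "
      f"{100 * (aif2.mean() / aif1.mean() - 1):+.1f}% "
      "(the AIF looks stable while the tissue estimates shift)")

a, b = result.study.pairs("injection", "PBV", regions="regional")
_, p = wilcoxon_signed_rank(a, b)
print(f"region-pooled Wilcoxon (PBV, injection 1 vs 2): p = {p:.2e}")

print("\nmechanism decomposition (noise-free, whole-lung medians):")
report = mechanism_report(design, residual_levels=(0.0, 0.79))
cols = ["residual", "mode", "aif_int_rel_err", "pbv_rel_err", "pbf_rel_err"]
print(report[cols].round(4).to_string(index=False))
print("\nlinear mode: residual contrast adds ~+4-5% PBV bias on top of the "
      "saturation floor; the corrected mode (known saturation + scheduled "
      "residual) removes it.")
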