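"""Regional heterogeneity and agreement statistics on paired measurements.

Computes the study-style heterogeneity measure (MAD: median over the 12
regions of |region median - whole-lung median|), the dorsoventral and
apicobasal perfusion gradients, and Bland-Altman + Wilcoxon comparisons
between two repeated acquisitions of the same phantom.
"""

import numpy as np

from lungdce import (
    PhantomSpec, bland_altman, generate_phantom, gradient_contrast,
    regional_mad, wilcoxon_signed_rank,
)
from lungdce.pipeline import quantify_series
from lungdce.regions import build_partition, summarize_regions
from dataclasses import replace


def regional_medians(seed):
    spec = PhantomSpec(noise_sd=2.0, sat_beta=0.0, seed=seed)
    series, _ = generate_phantom(spec)
    res = quantify_series(series)
    part = build_partition(series.lung_mask, spec.voxel_size_mm)
    summ = summarize_regions(res.maps, part)
    regional = summ.table[summ.table.region_id > 0].reset_index(drop=True)
    return regional, summ.whole_lung()


regional, whole = regional_medians(seed=1)

mad_pbv = regional_mad(regional.pbv, whole.pbv)
mad_pbf = regional_mad(regional.pbf, whole.pbf)
print(f"regional heterogeneity (MAD): PBV {mad_pbv:.2f} ml/100ml, "
      f"PBF {mad_pbf:.1f} ml/min/100ml")

dv = gradient_contrast(regional, "dorsoventral", "pbv")
ab = gradient_contrast(regional, "apicobasal", "pbv")
print(f"dorsoventral PBV contrast (back - front): {dv:+.2f} ml/100ml")
print(f"apicobasal PBV contrast (upper - lower):  {ab:+.2f} ml/100ml")

# test-retest: two noise realizations of the same subject
retest, _ = regional_medians(seed=2)
ba = bland_altman(regional.pbv, retest.pbv)
w, p = wilcoxon_signed_rank(regional.pbv, retest.pbv)
print(f"\ntest-retest PBV agreement over 12 regions:")
print(f"  mean difference {ba.mean_diff:+.3f} ml/100ml, "
      f"95% limits of agreement [{ba.loa_low:+.2f}, {ba.loa_high:+.2f}]")
print(f"  Wilcoxon signed-rank p = {p:.3f}")
print("  (same truth, independent noise: differences are sampling noise, "
      "so p fluctuates uniformly and occasionally dips below 0.05)")
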