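"""Quantify a phantom acquisition end to end and compare with ground truth.

Pipeline: bolus-arrival detection on the trunk signal -> relative-
enhancement conversion -> automatic AIF voxel detection -> truncated-SVD
deconvolution -> voxelwise MTT/PBF/PBV -> equal-volume regional medians.
"""

import numpy as np

from lungdce import PhantomSpec, generate_phantom
from lungdce.pipeline import quantify_series
from lungdce.regions import build_partition, summarize_regions

spec = PhantomSpec(noise_sd=2.0, sat_beta=0.0, seed=7)
series, truth = generate_phantom(spec)

result = quantify_series(series)  # fully automatic: no masks supplied
print(f"detected bolus arrival: frame {result.arrival_frame}")
print(f"AIF from {result.aif.source_voxel_count} automatically detected "
      f"voxels, integral {result.aif.integral:.3f} (arb. units x s)")
print(f"invalid voxel fraction: {result.maps.invalid_fraction:.4f}")

partition = build_partition(series.lung_mask, spec.voxel_size_mm)
summary = summarize_regions(result.maps, partition)

merged = summary.table.merge(
    truth.region_table[["region_id", "pbf", "pbv", "mtt_s"]],
    on="region_id", suffixes=("_est", "_true"))
merged["pbf_err_pct"] = 100 * (merged.pbf_est / merged.pbf_true - 1)
merged["pbv_err_pct"] = 100 * (merged.pbv_est / merged.pbv_true - 1)

print("\nper-region median estimates vs truth:")
print(merged[["name", "pbf_est", "pbf_true", "pbf_err_pct",
              "pbv_est", "pbv_true", "pbv_err_pct"]]
      .round(2).to_string(index=False))

whole = summary.whole_lung()
print(f"\nwhole lung: MTT {whole.mtt_s:.2f} s, "
      f"PBF {whole.pbf:.0f} ml/min/100ml, PBV {whole.pbv:.1f} ml/100ml")
print("(recovery errors of a few percent reflect 2% signal noise and the "
      "finite 35 s acquisition window)")
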