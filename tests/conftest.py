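import numpy as np
import pytest

from lungdce import PhantomSpec, generate_phantom
from lungdce.pipeline import quantify_series
from lungdce.regions import build_partition, summarize_regions


@pytest.fixture(scope="session")
def linear_spec():
    """Noise-free, linear-signal, residual-free phantom spec."""
    return PhantomSpec(noise_sd=0.0, sat_beta=0.0, seed=11)


@pytest.fixture(scope="session")
def linear_phantom(linear_spec):
    return generate_phantom(linear_spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sd=2.0, sat_beta=0.0, seed=11)
    return spec, generate_phantom(spec)


def region_errors(spec, series, gt, result):
    """Relative error (%) of per-region medians against ground truth."""
    part = build_partition(series.lung_mask, spec.voxel_size_mm)
    summ = summarize_regions(result.maps, part)
    merged = summ.table.merge(
        gt.region_table[["region_id", "pbf", "pbv", "mtt_s"]],
        on="region_id", suffixes=("_est", "_true"))
    return {
        "pbf": 100 * (merged.pbf_est / merged.pbf_true - 1).to_numpy(),
        "pbv": 100 * (merged.pbv_est / merged.pbv_true - 1).to_numpy(),
        "mtt": 100 * (merged.mtt_s_est / merged.mtt_s_true - 1).to_numpy(),
    }


@pytest.fixture(scope="session")
def quantified_linear(linear_spec, linear_phantom):
    series, gt = linear_phantom
    res = quantify_series(series)
    return linear_spec, series, gt, res
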