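"""Equal-volume partitioning, vessel exclusion, regional summaries."""

import numpy as np
import pytest

from lungdce import (
    ComputeError,
    ValidationError,
    build_partition,
    exclude_vessels,
    generate_phantom,
    partition_lung,
    split_lungs,
    summarize_regions,
)
from lungdce.deconv import PerfusionMaps
from lungdce.phantom import PhantomSpec
from lungdce.pipeline import quantify_series


def random_lung_mask(rng, shape=(20, 18, 12)):
    """A random blobby single-lung mask with at least 3 z planes."""
    mask = rng.random(shape) < 0.45
    mask[..., :2] = False  # ensure some empty planes exist sometimes
    # guarantee 3 populated z planes
    for z in (3, 6, 9):
        mask[5:12, 5:12, z] = True
    return mask


class TestSplitLungs:
    def test_two_boxes_assigned_by_centroid(self):
        mask = np.zeros((20, 10, 10), bool)
        mask[2:7, 2:8, 2:8] = True
        mask[12:18, 2:8, 2:8] = True
        left, right = split_lungs(mask)
        expected_left = np.zeros_like(mask)
        expected_left[2:7, 2:8, 2:8] = True
        assert np.array_equal(left, expected_left)
        assert not right[2:7].any() and right[12:18, 2:8, 2:8].all()
        assert (left | right).sum() == mask.sum()

    def test_single_blob_rejected(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        with pytest.raises(ComputeError, match="not separable"):
            split_lungs(mask)

    def test_phantom_masks_split_matches_generator(self, linear_phantom):
        series, _ = linear_phantom
        left, right = split_lungs(series.lung_mask)
        labels = series.region_labels
        assert set(np.unique(labels[left])) - {0} == set(range(1, 7))
        assert set(np.unique(labels[right])) - {0} == set(range(7, 13))


class TestPartitionLung:
    def test_divisible_cuboid_gives_exact_sixths(self):
        mask = np.zeros((10, 2, 6), bool)
        mask[:, :, :] = True  # 120 voxels; 6 z planes x 2 y planes
        labels = partition_lung(mask)
        counts = [(labels == k).sum() for k in range(1, 7)]
        assert counts == [20] * 6

    def test_imbalance_bounded_by_one_plane(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = random_lung_mask(rng)
            labels = partition_lung(mask)
            # disjoint cover
            assert ((labels > 0) == mask).all()
            slab = [(np.isin(labels, (2 * s + 1, 2 * s + 2))).sum()
                    for s in range(3)]
            n, max_plane = mask.sum(), mask.sum(axis=(0, 1)).max()
            # nearest-plane cuts: outer slabs deviate from n/3 by at most
            # half a plane; the middle slab absorbs both cut errors
            assert abs(slab[0] - n / 3) <= max_plane / 2 + 1
            assert abs(slab[2] - n / 3) <= max_plane / 2 + 1
            assert max(slab) - min(slab) <= 1.5 * max_plane + 1
            for s in range(3):
                front = (labels == 2 * s + 1).sum()
                back = (labels == 2 * s + 2).sum()
                slab_mask = np.isin(labels, (2 * s + 1, 2 * s + 2))
                max_y_plane = slab_mask.sum(axis=(0, 2)).max()
                assert abs(front - back) <= max_y_plane

    def test_deterministic_and_order_free(self):
        rng = np.random.default_rng(1)
        mask = random_lung_mask(rng)
        a = partition_lung(mask)
        b = partition_lung(np.array(mask, order="F"))
        assert np.array_equal(a, b)

    def test_thin_lung_rejected(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[:, :, 2] = True
        with pytest.raises(ValidationError):
            partition_lung(mask)


class TestExcludeVessels:
    def _uniform_maps(self, shape=(12, 12, 8)):
        rng = np.random.default_rng(0)
        mask = np.ones(shape, bool)
        pbv = rng.uniform(10, 30, size=shape)  # continuous: exact percentile
        return PerfusionMaps(mtt_s=np.full(shape, 5.0), pbf=pbv * 12,
                             pbv=pbv, valid_mask=mask), mask

    def test_percentile_contract_on_uniform_map(self):
        maps, mask = self._uniform_maps()
        filtered = exclude_vessels(maps, mask, pbv_percentile=95)
        removed = mask.sum() - filtered.sum()
        # 5% above threshold plus their 1-voxel dilation halo
        assert removed >= 0.05 * mask.sum() * 0.9
        assert removed < 0.45 * mask.sum()

    def test_phantom_vessels_all_removed(self):
        spec = PhantomSpec(noise_sd=0.0, vessel_fraction=0.01, seed=4)
        series, gt = generate_phantom(spec)
        res = quantify_series(series)
        lung = series.region_labels > 0
        filtered = exclude_vessels(res.maps, lung, pbv_percentile=95)
        assert not filtered[gt.vessel_mask].any()

    def test_vessel_free_medians_barely_change(self, quantified_linear):
        spec, series, gt, res = quantified_linear
        lung = series.region_labels > 0
        filtered = exclude_vessels(res.maps, lung, pbv_percentile=95)
        part = build_partition(lung, spec.voxel_size_mm)
        before = summarize_regions(res.maps, part).whole_lung()
        maps2 = PerfusionMaps(res.maps.mtt_s, res.maps.pbf, res.maps.pbv,
                              res.maps.valid_mask & filtered)
        after = summarize_regions(maps2, part).whole_lung()
        for col in ("mtt_s", "pbf", "pbv"):
            assert abs(after[col] / before[col] - 1.0) < 0.01

    def test_percentile_validated(self, quantified_linear):
        spec, series, gt, res = quantified_linear
        with pytest.raises(ValidationError):
            exclude_vessels(res.maps, series.lung_mask, pbv_percentile=40)


class TestSummarizeRegions:
    def test_constant_maps_give_constant_medians(self):
        mask = np.zeros((20, 10, 12), bool)
        mask[2:8, 2:8, 2:10] = True
        mask[12:18, 2:8, 2:10] = True
        part = build_partition(mask)
        maps = PerfusionMaps(
            mtt_s=np.full(mask.shape, 5.0), pbf=np.full(mask.shape, 240.0),
            pbv=np.full(mask.shape, 20.0), valid_mask=mask)
        summ = summarize_regions(maps, part)
        assert (summ.table.mtt_s == 5.0).all()
        assert (summ.table.n_valid > 0).all()

    def test_whole_lung_median_within_region_range(self, quantified_linear):
        spec, series, gt, res = quantified_linear
        part = build_partition(series.lung_mask, spec.voxel_size_mm)
        summ = summarize_regions(res.maps, part)
        regional = summ.table[summ.table.region_id > 0]
        whole = summ.whole_lung()
        assert regional.pbv.min() <= whole.pbv <= regional.pbv.max()

    def test_region_without_valid_voxels_marked_missing(self):
        mask = np.zeros((20, 10, 12), bool)
        mask[2:8, 2:8, 2:10] = True
        mask[12:18, 2:8, 2:10] = True
        part = build_partition(mask)
        valid = mask & (part.labels != 3)
        maps = PerfusionMaps(
            mtt_s=np.full(mask.shape, 5.0), pbf=np.full(mask.shape, 240.0),
            pbv=np.full(mask.shape, 20.0), valid_mask=valid)
        summ = summarize_regions(maps, part)
        row = summ.region(3)
        assert row.n_valid == 0 and np.isnan(row.pbv)


def test_partition_table_covers_twelve_regions(linear_phantom):
    series, _ = linear_phantom
    part = build_partition(series.lung_mask)
    assert len(part.table) == 12
    assert part.table.voxel_count.sum() == series.lung_mask.sum()
    # labels and table agree
    for _, row in part.table.iterrows():
        assert (part.labels == row.region_id).sum() == row.voxel_count
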