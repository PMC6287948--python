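"""Synthetic phantom: AIF shape, tracer kinetics, signal model, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from lungdce import (
    AifParams,
    PhantomSpec,
    ValidationError,
    generate_aif,
    generate_phantom,
    signal_from_concentration,
    tissue_curve_from_truth,
)
from lungdce.phantom import aif_analytic_integral, default_region_truth

DT = 1.47


class TestGenerateAif:
    def test_zero_before_injection_without_residual(self):
        aif = generate_aif(AifParams(), 24, DT, injection_delay_s=5.0)
        onset_frame = int((5.0 + 3.0) // DT)
        assert np.all(aif[:onset_frame] == 0.0)
        assert aif[onset_frame:].max() > 0

    def test_residual_plateau_additive(self):
        p = AifParams(steady_state_conc=0.04)
        base = generate_aif(p, 24, DT, residual_fraction=0.0)
        shifted = generate_aif(p, 24, DT, residual_fraction=0.5)
        np.testing.assert_allclose(shifted, base + 0.5 * 0.04, rtol=1e-12)
        # first-pass peak unchanged in concentration space
        assert np.isclose(shifted.max() - 0.5 * 0.04, base.max())

    def test_first_enhanced_frame_index(self):
        # injection at 5 s, trunk arrival 3 s, dt 1.47 s: frame floor(8/1.47)=5
        aif = generate_aif(AifParams(trunk_arrival_s=3.0), 24, DT,
                           injection_delay_s=5.0)
        first = int(np.flatnonzero(aif > 0)[0])
        assert first == 5

    def test_peak_after_scan_end_rejected(self):
        with pytest.raises(ValidationError):
            generate_aif(AifParams(scale_tp_s=60.0), 24, DT)

    def test_recirculation_adds_late_mass(self):
        p0 = AifParams()
        p1 = AifParams(recirc_amplitude=0.2, recirc_delay_s=10.0)
        a0 = generate_aif(p0, 24, DT)
        a1 = generate_aif(p1, 24, DT)
        assert a1.sum() > a0.sum()
        assert np.all(a1 >= a0 - 1e-15)


class TestTissueCurve:
    def test_delta_aif_gives_scaled_geometric_residue(self):
        n = 24
        aif = np.zeros(n)
        aif[0] = 2.0  # all mass in one frame, integral A = 2*dt
        pbf, pbv = 240.0, 20.0
        ct = tissue_curve_from_truth(aif, pbf, pbv, DT)
        f = pbf / 6000.0
        mtt = 60.0 * pbv / pbf
        assert np.isclose(mtt, 5.0)  # 60*20/240
        q = 1.0 - DT / mtt
        expected = DT * 2.0 * f * q ** np.arange(n)
        np.testing.assert_allclose(ct, expected, rtol=1e-12)
        # peak ratio C_t(0) / (A = integral of AIF) equals f
        assert np.isclose(ct[0] / (2.0 * DT), f)

    def test_integral_ratio_recovers_pbv_untruncated(self):
        # conservation: with a window many MTTs long the tissue/arterial
        # integral ratio equals PBV/100 to better than 1%
        n = 48
        aif = generate_aif(AifParams(), n, DT)
        ct = tissue_curve_from_truth(aif, 240.0, 20.0, DT)
        ratio = ct.sum() / aif.sum()
        assert abs(ratio / 0.20 - 1.0) < 0.01

    def test_mtt_below_frame_interval_rejected(self):
        aif = generate_aif(AifParams(), 24, DT)
        with pytest.raises(ValidationError):
            tissue_curve_from_truth(aif, pbf=6000.0, pbv=1.0, dt_s=DT)  # MTT 0.01 s


class TestSignalModel:
    def test_zero_concentration_identity(self):
        assert signal_from_concentration(0.0, 100.0, 0.5) == 100.0

    def test_linear_case(self):
        assert np.isclose(signal_from_concentration(0.5, 100.0, 0.0), 150.0)

    def test_saturation_asymptote(self):
        s = signal_from_concentration(1e9, 100.0, 1.0)
        assert np.isclose(s, 200.0, rtol=1e-6)

    def test_monotone_and_concave(self):
        c = np.linspace(0, 5, 400)
        s = signal_from_concentration(c, 100.0, 0.7)
        d1 = np.diff(s)
        assert np.all(d1 > 0)
        assert np.all(np.diff(d1) <= 1e-9)

    def test_marginal_enhancement_decreases_with_baseline(self):
        # the dampening mechanism: the same increment on a higher baseline
        # produces less signal change when the map saturates
        inc = [signal_from_concentration(c0 + 0.1, 100.0, 0.5)
               - signal_from_concentration(c0, 100.0, 0.5)
               for c0 in (0.0, 0.5, 1.0)]
        assert inc[0] > inc[1] > inc[2]

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            signal_from_concentration(-0.1, 100.0, 0.0)


class TestGeneratePhantom:
    def test_noiseless_linear_voxels_match_analytic_curves(self, linear_phantom):
        series, gt = linear_phantom
        labels = series.region_labels
        s0 = 100.0
        for rid in (1, 8):
            reg = gt.region_table[gt.region_table.region_id == rid].iloc[0]
            expected_conc = tissue_curve_from_truth(
                gt.aif_first_pass, reg.pbf, reg.pbv, series.dt_s,
                delay_frames=gt.delay_frames)
            voxel = series.data[labels == rid][0]
            np.testing.assert_allclose(voxel, s0 * (1 + expected_conc), rtol=1e-10)

    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(seed=5)
        a, _ = generate_phantom(spec)
        b, _ = generate_phantom(PhantomSpec(seed=5))
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a, _ = generate_phantom(PhantomSpec(seed=5))
        b, _ = generate_phantom(PhantomSpec(seed=6))
        assert not np.array_equal(a.data, b.data)

    def test_dorsal_truth_exceeds_ventral(self, linear_phantom):
        _, gt = linear_phantom
        t = gt.region_table
        assert (t[t.depth == "back"].pbv.mean()
                > t[t.depth == "front"].pbv.mean())

    def test_missing_region_truth_rejected(self):
        truth = default_region_truth().iloc[:-1]
        with pytest.raises(ValidationError, match="missing"):
            generate_phantom(PhantomSpec(region_truth=truth))

    def test_residual_fraction_range_enforced(self):
        with pytest.raises(ValidationError):
            PhantomSpec(residual_fraction=1.5).validate()

    def test_truth_satisfies_central_volume_identity(self, linear_phantom):
        _, gt = linear_phantom
        t = gt.region_table
        np.testing.assert_allclose(t.mtt_s * t.pbf / 60.0, t.pbv, rtol=1e-12)

    @pytest.mark.parametrize("arrival_s", [2.4, 4.0, 5.5, 7.0, 8.2])
    def test_unenhanced_frame_count_in_protocol_range(self, arrival_s):
        # arrival delays of 2.4-8.2 s after a 5 s injection delay give
        # 5-8 frames without enhancement at 1.47 s/frame
        spec = PhantomSpec(aif_params=AifParams(trunk_arrival_s=arrival_s),
                           noise_sd=0.0)
        _, gt = generate_phantom(spec)
        assert 5 <= gt.arrival_frame <= 8

    def test_smooth_gradient_mode_orders_voxel_truth(self):
        spec = PhantomSpec(noise_sd=0.0, smooth_gradient=True)
        series, gt = generate_phantom(spec)
        lung = series.region_labels > 0
        ys = np.nonzero(lung)[1]
        pbv = gt.pbv[lung]
        front = pbv[ys < np.median(ys)].mean()
        back = pbv[ys >= np.median(ys)].mean()
        assert back > front

    def test_vessel_voxels_carry_high_pbv(self):
        spec = PhantomSpec(noise_sd=0.0, vessel_fraction=0.01)
        series, gt = generate_phantom(spec)
        assert gt.vessel_mask.sum() >= 1
        lung = series.region_labels > 0
        parenchyma = lung & ~gt.vessel_mask
        assert gt.pbv[gt.vessel_mask].min() > np.nanmax(gt.pbv[parenchyma])


def test_analytic_gamma_integral_matches_numeric():
    p = AifParams()
    n = 64  # long window so the tail is fully covered
    aif = generate_aif(p, n, DT)
    assert np.isclose(aif.sum() * DT, aif_analytic_integral(p), rtol=1e-3)
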