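"""AP detection, APD measurement, Bazett correction and IV analysis."""

import numpy as np
import pytest

from cardiomir.simulate import APWaveformParams, simulate_ap_trace
from cardiomir.traces import (
    APConfig,
    IVCurve,
    RatioTrace,
    analyze_cell,
    apd_at_level,
    average_ap,
    bazett_correct,
    cfpd,
    detect_aps,
    drug_subtract,
    extract_fpd,
    iv_curve,
    leak_subtract,
    ratio_trace,
)


class TestBazett:
    def test_identity_at_one_second_rr(self):
        assert bazett_correct(400.0, 1000.0) == pytest.approx(400.0)

    def test_worked_example(self):
        assert bazett_correct(400.0, 640.0) == pytest.approx(500.0)

    def test_zero_duration(self):
        assert bazett_correct(0.0, 800.0) == 0.0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            bazett_correct(400.0, 0.0)

    def test_monotone_decreasing_in_rr(self):
        rrs = np.linspace(400, 2000, 30)
        vals = [bazett_correct(300.0, r) for r in rrs]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_cfpd_worked_example(self):
        assert cfpd(300.0, 1000.0) == pytest.approx(300.0)
        assert cfpd(300.0, 2250.0) == pytest.approx(200.0)


class TestRatioTrace:
    def test_constant_channels(self):
        t = np.arange(0, 100.0)
        tr = ratio_trace(np.full(100, 4.0), np.full(100, 2.0), t)
        assert np.allclose(tr.signal, 2.0)

    def test_identical_channels_unity(self):
        t = np.arange(0, 50.0)
        x = np.random.default_rng(0).uniform(1, 5, 50)
        assert np.allclose(ratio_trace(x, x, t).signal, 1.0)

    def test_nonpositive_denominator_flagged(self):
        t = np.arange(0, 10.0)
        den = np.ones(10)
        den[3] = 0.0
        tr = ratio_trace(np.ones(10), den, t)
        assert tr.metadata["n_bad_denominator"] == 1
        assert np.isnan(tr.signal[3])

    def test_jitter_rejected(self):
        t = np.array([0.0, 1.0, 2.5, 3.0])
        with pytest.raises(ValueError):
            RatioTrace(time=t, signal=np.zeros(4))


class TestDetectAPs:
    def test_flat_noise_trace_empty(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 5000.0)
        tr = RatioTrace(time=t, signal=1.0 + rng.normal(0, 0.02, len(t)))
        assert len(detect_aps(tr)) == 0

    def test_noiseless_five_beats_within_one_sample(self):
        p = APWaveformParams(
            upstroke_duration=0.0, plateau_duration=200.0,
            repolarization_duration=200.0, beat_interval=800.0,
            n_beats=5, sampling_interval=1.0, noise_sd=0.0, rng_seed=0,
        )
        trace, truth = simulate_ap_trace(p)
        idx = detect_aps(trace)
        assert len(idx) == 5
        assert np.all(np.abs(trace.time[idx] - truth.onset_times) <= p.sampling_interval)

    def test_drift_and_noise_invariance(self):
        p = APWaveformParams(
            upstroke_duration=0.0, plateau_duration=200.0,
            repolarization_duration=200.0, beat_interval=800.0,
            n_beats=5, sampling_interval=1.0, noise_sd=0.1, drift_per_s=0.05,
            rng_seed=3,
        )
        trace, truth = simulate_ap_trace(p)
        idx = detect_aps(trace)
        assert len(idx) == 5
        assert np.all(np.abs(trace.time[idx] - truth.onset_times) <= 10.0)

    def test_minimum_length_enforced(self):
        t = np.arange(0, 500.0)
        with pytest.raises(ValueError):
            detect_aps(RatioTrace(time=t, signal=np.zeros_like(t)))


class TestAPDAtLevel:
    def _trace_and_upstroke(self, params):
        trace, _ = simulate_ap_trace(params)
        idx = detect_aps(trace)
        return trace, idx

    def test_square_pulse_apd90_380ms(self, square_ap_params):
        trace, idx = self._trace_and_upstroke(square_ap_params)
        apd = apd_at_level(trace, idx[1], level=0.9,
                           next_upstroke_index=idx[2], prev_upstroke_index=idx[0])
        assert apd == pytest.approx(380.0, abs=square_ap_params.sampling_interval)

    def test_apd50_of_same_waveform(self, square_ap_params):
        trace, idx = self._trace_and_upstroke(square_ap_params)
        apd = apd_at_level(trace, idx[1], level=0.5,
                           next_upstroke_index=idx[2], prev_upstroke_index=idx[0])
        assert apd == pytest.approx(300.0, abs=square_ap_params.sampling_interval)

    def test_affine_invariance(self, square_ap_params):
        trace, idx = self._trace_and_upstroke(square_ap_params)
        scaled = RatioTrace(time=trace.time, signal=3.0 * trace.signal + 7.0)
        a1 = apd_at_level(trace, idx[1], 0.9, next_upstroke_index=idx[2],
                          prev_upstroke_index=idx[0])
        a2 = apd_at_level(scaled, idx[1], 0.9, next_upstroke_index=idx[2],
                          prev_upstroke_index=idx[0])
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_truncated_repolarization_invalid(self):
        # trace ends mid-plateau of the final beat
        p = APWaveformParams(
            upstroke_duration=0.0, plateau_duration=200.0,
            repolarization_duration=200.0, beat_interval=700.0,
            n_beats=3, sampling_interval=1.0, noise_sd=0.0, rng_seed=0,
        )
        trace, _ = simulate_ap_trace(p)
        # cut mid-repolarization of beat 3, before the 90% crossing
        cut = int((350.0 + 2 * 700.0 + 360.0))
        trace = RatioTrace(time=trace.time[:cut], signal=trace.signal[:cut])
        idx = detect_aps(trace)
        assert apd_at_level(trace, idx[-1], 0.9,
                            prev_upstroke_index=idx[-2]) is None


class TestAverageAP:
    def test_idempotent_on_identical_noiseless_aps(self, square_ap_params):
        trace, _ = simulate_ap_trace(square_ap_params)
        idx = detect_aps(trace)
        rel_t, mean = average_ap(trace, idx, n=5)
        single = trace.signal[idx[0]: idx[0] + len(mean)]
        assert np.allclose(mean, single, atol=1e-9)

    def test_noise_suppression_scales_with_n(self):
        p = APWaveformParams(
            upstroke_duration=0.0, plateau_duration=200.0,
            repolarization_duration=200.0, beat_interval=640.0,
            n_beats=20, sampling_interval=1.0, noise_sd=0.05, rng_seed=6,
        )
        trace, _ = simulate_ap_trace(p)
        clean, _ = simulate_ap_trace(
            APWaveformParams(**{**p.__dict__, "noise_sd": 0.0})
        )
        idx = detect_aps(trace)
        _, mean = average_ap(trace, idx, n=15)
        ref = clean.signal[idx[0]: idx[0] + len(mean)]
        resid = np.std(mean - ref)
        assert resid < 3 * p.noise_sd / np.sqrt(15)

    def test_fallback_when_fewer_aps(self, square_ap_params):
        trace, _ = simulate_ap_trace(square_ap_params)
        idx = detect_aps(trace)[:5]
        rel_t, mean = average_ap(trace, idx, n=15)  # logs a warning, uses 5
        assert len(mean) > 0

    def test_fewer_than_two_aps_rejected(self, square_ap_params):
        trace, _ = simulate_ap_trace(square_ap_params)
        with pytest.raises(ValueError):
            average_ap(trace, [10], n=15)


class TestAnalyzeCell:
    def test_capd90_recovery(self, square_ap_params):
        trace, _ = simulate_ap_trace(square_ap_params)
        cell = analyze_cell(trace)
        assert cell.median_capd90 == pytest.approx(380.0 / np.sqrt(0.64), rel=0.02)
        assert cell.median_rr == pytest.approx(640.0, rel=0.01)

    def test_truncated_trace_flagged(self):
        p = APWaveformParams(n_beats=1, beat_interval=1200.0, noise_sd=0.0, rng_seed=0)
        trace, _ = simulate_ap_trace(p)
        cell = analyze_cell(trace)
        assert cell.flagged

    def test_permutation_and_batch_independence(self, square_ap_params):
        trace, _ = simulate_ap_trace(square_ap_params)
        c1 = analyze_cell(trace)
        c2 = analyze_cell(trace)  # stateless: same output on reanalysis
        assert c1 == c2


class TestIVAnalysis:
    def test_peak_mode_signed_extremum(self):
        tr = np.concatenate([np.zeros(10), np.linspace(0, -500, 20), np.full(20, -100.0)])
        curve = iv_curve([(-10.0, tr)], capacitance=25.0, mode="peak")
        assert curve.densities[0] == pytest.approx(-20.0)

    def test_end_mode_terminal_mean(self):
        tr = np.concatenate([np.linspace(0, 200, 50), np.full(50, 200.0)])
        curve = iv_curve([(40.0, tr)], capacitance=20.0, mode="end")
        assert curve.densities[0] == pytest.approx(10.0)

    def test_zero_current(self):
        curve = iv_curve([(0.0, np.zeros(100))], capacitance=30.0, mode="peak")
        assert curve.densities[0] == 0.0

    def test_capacitance_linearity(self):
        tr = np.linspace(0, -400, 50)
        c1 = iv_curve([(-20.0, tr)], capacitance=10.0)
        c2 = iv_curve([(-20.0, tr)], capacitance=20.0)
        assert c1.densities[0] == pytest.approx(2 * c2.densities[0])

    def test_drug_subtraction(self):
        v = np.array([-40.0, 0.0, 40.0])
        ctrl = IVCurve(v, np.array([1.0, 3.0, 5.0]), 20.0)
        drug = IVCurve(v, np.array([0.5, 1.0, 2.0]), 20.0)
        diff = drug_subtract(ctrl, drug)
        assert np.allclose(diff.densities, [0.5, 2.0, 3.0])

    def test_drug_equals_control_zero(self):
        v = np.array([-40.0, 40.0])
        c = IVCurve(v, np.array([2.0, 4.0]), 15.0)
        assert np.allclose(drug_subtract(c, c).densities, 0.0)

    def test_mismatched_grids_rejected(self):
        c1 = IVCurve(np.array([-40.0, 40.0]), np.zeros(2), 15.0)
        c2 = IVCurve(np.array([-30.0, 40.0]), np.zeros(2), 15.0)
        with pytest.raises(ValueError):
            drug_subtract(c1, c2)

    def test_leak_subtraction_zeroes_ohmic_curve(self):
        v = np.linspace(-80, 40, 13)
        ohmic = IVCurve(v, 0.05 * v + 1.2, 20.0)
        corrected = leak_subtract(ohmic, fit_range=(-80.0, -50.0))
        assert np.allclose(corrected.densities, 0.0, atol=1e-10)


class TestFPDExtractor:
    def test_recovers_spike_to_repolarization_interval(self):
        t = np.arange(0, 1500.0)
        y = np.zeros_like(t)
        y[200] = -4.0            # depolarization spike
        y[500:520] = 1.5         # repolarization hump at +300 ms
        fpd = extract_fpd(t, y)
        assert fpd == pytest.approx(300.0, abs=25.0)
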