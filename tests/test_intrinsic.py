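"""Intrinsic feature extraction: definitions, analytic constructions, and
oracle equivalence against brute-force implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_recording, make_sweep
from oracles import half_width_scan, ols_slope, third_derivative_threshold
from ephyskit.io import VOLTAGE_CLAMP, ValidationError
from ephyskit.intrinsic import (AnalysisWindows, FeatureUndefined, SpikeTrain,
                                ap_amplitude, ap_half_width, ap_threshold,
                                detect_all_spikes, detect_spikes, extract_all,
                                firing_metrics, input_resistance, measure_ahp,
                                membrane_time_constant, qc_intrinsic,
                                resting_potential)


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

class TestDetectSpikes:
    def test_constant_trace_has_no_spikes(self):
        tr = detect_spikes(make_sweep(np.full(4000, -67.0)))
        assert tr.n_spikes == 0

    def test_crossing_times_are_interpolated(self):
        v = np.full(500, -10.0)
        v[101:120] = 10.0      # upward crossing between samples 100 and 101
        v[301:320] = 10.0      # and between 300 and 301
        tr = detect_spikes(make_sweep(v))
        assert tr.n_spikes == 2
        np.testing.assert_allclose(tr.times_ms, [5.025, 15.025], atol=0.05)
        # frequency count = spike count − 1
        assert tr.instantaneous_freq_hz.size == 1
        assert tr.instantaneous_freq_hz[0] == pytest.approx(100.0, rel=0.01)

    def test_voltage_clamp_sweep_is_a_mode_error(self):
        sw = make_sweep(np.zeros(100), mode=VOLTAGE_CLAMP)
        with pytest.raises(ValidationError, match="mode"):
            detect_spikes(sw)

    def test_simulated_spikes_match_generator_log(self, young_recording):
        rec, gt = young_recording
        for j, tr in enumerate(detect_all_spikes(rec)):
            true = gt.spike_times_ms[j]
            assert tr.n_spikes == true.size
            if true.size:
                assert np.max(np.abs(tr.times_ms - true)) < 0.1


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------

class TestPassive:
    def test_resting_potential_of_constant_trace(self):
        sw = make_sweep(np.full(4000, -67.0))
        assert resting_potential(sw) == pytest.approx(-67.0)

    def test_resting_potential_averages_noise(self, rng):
        sw = make_sweep(-67.0 + rng.normal(0, 0.5, 4000))
        # pre-stimulus segment is 3000 samples; SEM ≈ 0.5/sqrt(3000)
        assert resting_potential(sw) == pytest.approx(-67.0, abs=0.05)

    def test_short_segment_is_an_error(self):
        sw = make_sweep(np.zeros(4000), onset=50.0)
        with pytest.raises(FeatureUndefined, match="100"):
            resting_potential(sw)

    def test_ohms_law(self):
        v = np.full(16001, -67.0)
        i_on, i_off = 3000, 8000
        v[i_on:i_off] = -72.0    # −5 mV at −50 pA → 100 MΩ
        sw = make_sweep(v, amplitude=-50.0)
        assert input_resistance(sw) == pytest.approx(100.0)

    def test_zero_deflection_warns_and_returns_zero(self):
        sw = make_sweep(np.full(16001, -67.0), amplitude=-50.0)
        with pytest.warns(UserWarning, match="zero deflection"):
            assert input_resistance(sw) == 0.0

    def test_wrong_sweep_amplitude_rejected(self):
        sw = make_sweep(np.zeros(16001), amplitude=-100.0)
        with pytest.raises(FeatureUndefined, match="-50"):
            input_resistance(sw)

    def test_tau_of_analytic_exponential(self):
        # V(t) = −67 − 5(1−e^(−t/20)); 63% level hit at 20·ln(1/0.37) ≈ 19.89
        dt = 0.05
        t = np.arange(16001) * dt
        v = np.full(16001, -67.0)
        on = t >= 150.0
        v[on] = -67.0 - 5.0 * (1 - np.exp(-(t[on] - 150.0) / 20.0))
        sw = make_sweep(v, amplitude=-50.0)
        assert membrane_time_constant(sw) == pytest.approx(19.89, abs=0.15)

    def test_tau_of_instant_step_is_at_most_dt(self):
        v = np.full(16001, -67.0)
        v[3000:8000] = -74.5
        sw = make_sweep(v, amplitude=-50.0)
        assert membrane_time_constant(sw) <= 0.05

    def test_simulator_recovery(self, quiet_recording):
        rec, gt = quiet_recording
        sw = rec.sweep_at(-50.0)
        assert input_resistance(sw) == pytest.approx(gt.true_rin_mohm,
                                                     rel=0.01)
        assert membrane_time_constant(sw) == pytest.approx(gt.true_tau_ms,
                                                           rel=0.03)


# ---------------------------------------------------------------------------
# AP waveform
# ---------------------------------------------------------------------------

def _splice_spike(dt=0.05):
    """Slow linear rise spliced to an accelerating quadratic at V = −55 mV:
    the second derivative jumps at the splice, so the discrete third
    derivative peaks there.  The quadratic reaches +30 mV within 2 ms and a
    linear fall returns to rest."""
    n = 4000
    v = np.full(n, -60.0)
    t_sp = 100.0
    falling = None
    for i in range(int(60.0 / dt), n):
        t = i * dt
        if t < t_sp:
            v[i] = -60.0 + 0.125 * (t - 60.0)          # slope 0.125 mV/ms
        elif falling is None:
            tau = t - t_sp
            v[i] = -55.0 + 0.125 * tau + 30.0 * tau ** 2
            if v[i] >= 30.0:
                falling = t
        else:
            v[i] = max(30.0 - 100.0 * (t - falling), -60.0)
    return v, t_sp


class TestAPWaveform:
    def test_no_spike_recording_has_undefined_threshold(self):
        sw = make_sweep(np.full(1000, -67.0))
        tr = detect_spikes(sw)
        with pytest.raises(FeatureUndefined, match="threshold"):
            ap_threshold(sw, tr)

    def test_threshold_found_at_curvature_splice(self):
        v, t_sp = _splice_spike()
        sw = make_sweep(v, onset=0.0, duration=200.0)
        tr = detect_spikes(sw)
        assert tr.n_spikes == 1
        thr = ap_threshold(sw, tr, smooth=False)
        assert thr == pytest.approx(-55.0, abs=0.5)

    def test_threshold_matches_brute_force_oracle(self, quiet_recording):
        from ephyskit.intrinsic import _ap_peak_index, _first_ap
        rec, _ = quiet_recording
        trains = detect_all_spikes(rec)
        sw, tr, _ = _first_ap(rec, trains)
        ours = ap_threshold(sw, tr, smooth=False)
        peak = _ap_peak_index(sw, tr.times_ms[0])
        oracle = third_derivative_threshold(sw.samples, sw.dt, peak)
        # within one sample's worth of voltage on the AP upstroke
        assert abs(ours - oracle) <= abs(np.diff(sw.samples)).max()

    def test_amplitude_is_peak_minus_threshold(self, quiet_recording):
        rec, _ = quiet_recording
        trains = detect_all_spikes(rec)
        from ephyskit.intrinsic import _first_ap
        sw, tr, _ = _first_ap(rec, trains)
        amp = ap_amplitude(sw, tr, -48.0)
        assert amp == pytest.approx(30.0 - (-48.0), abs=0.5)

    def test_half_width_of_asymmetric_triangle(self):
        # threshold −50, rise to +30 in 1 ms, fall back in 2 ms → 1.5 ms
        dt = 0.05
        v = np.full(2000, -50.0)
        i0 = 400
        up = int(1.0 / dt)
        down = int(2.0 / dt)
        v[i0:i0 + up + 1] = np.linspace(-50.0, 30.0, up + 1)
        v[i0 + up:i0 + up + down + 1] = np.linspace(30.0, -50.0, down + 1)
        sw = make_sweep(v, onset=0.0, duration=100.0)
        tr = detect_spikes(sw)
        hw = ap_half_width(sw, tr, -50.0, 80.0)
        assert hw == pytest.approx(1.5, abs=0.05)

    def test_half_width_of_symmetric_triangle(self):
        dt = 0.05
        v = np.full(2000, -50.0)
        i0, w = 400, int(1.0 / dt)
        v[i0:i0 + w + 1] = np.linspace(-50.0, 30.0, w + 1)
        v[i0 + w:i0 + 2 * w + 1] = np.linspace(30.0, -50.0, w + 1)
        sw = make_sweep(v, onset=0.0, duration=100.0)
        tr = detect_spikes(sw)
        assert ap_half_width(sw, tr, -50.0, 80.0) == pytest.approx(1.0,
                                                                   abs=0.05)

    def test_half_width_matches_dense_scan_oracle(self, quiet_recording):
        from ephyskit.intrinsic import _ap_peak_index, _first_ap
        rec, _ = quiet_recording
        trains = detect_all_spikes(rec)
        sw, tr, _ = _first_ap(rec, trains)
        thr = ap_threshold(sw, tr, smooth=False)
        amp = ap_amplitude(sw, tr, thr)
        ours = ap_half_width(sw, tr, thr, amp)
        peak = _ap_peak_index(sw, tr.times_ms[0])
        oracle = half_width_scan(sw.samples, sw.dt, peak, thr + amp / 2)
        assert abs(ours - oracle) <= sw.dt


# ---------------------------------------------------------------------------
# firing metrics
# ---------------------------------------------------------------------------

def _train(idx, times):
    times = np.asarray(times, dtype=float)
    isi = np.diff(times)
    return SpikeTrain(sweep_index=idx, times_ms=times,
                      instantaneous_freq_hz=1000.0 / isi if isi.size
                      else np.empty(0))


def _protocol_recording(amplitudes):
    sweeps = [make_sweep(np.full(24001, -67.0), amplitude=a)
              for a in amplitudes]
    return make_recording(sweeps)


class TestFiringMetrics:
    def test_max_frequency_is_shortest_isi(self):
        rec = _protocol_recording([100.0, 150.0, 200.0])
        trains = [_train(0, [160, 170]), _train(1, [160, 165]),
                  _train(2, [160, 180])]
        fm = firing_metrics(trains, rec)
        assert fm.max_freq_hz == pytest.approx(200.0)

    def test_fi_slope_on_exact_linear_data(self):
        amps = list(range(150, 701, 50))
        rec = _protocol_recording([float(a) for a in amps])
        trains = []
        for i, a in enumerate(amps):
            f = 0.2 * (a - 100.0)              # Hz
            isi = 1000.0 / f
            trains.append(_train(i, [160.0, 160.0 + isi]))
        fm = firing_metrics(trains, rec)
        assert fm.fi_slope_hz_per_pa == pytest.approx(0.2, rel=1e-9)

    def test_adaptation_index_at_250_above_first_spiking(self):
        amps = [float(a) for a in range(150, 701, 50)]
        rec = _protocol_recording(amps)
        trains = [_train(i, []) for i in range(len(amps))]
        trains[0] = _train(0, [160.0, 180.0])              # first spiking 150
        j400 = amps.index(400.0)
        trains[j400] = _train(j400, [160.0, 170.0, 190.0])  # ISIs 10, 20 ms
        fm = firing_metrics(trains, rec)
        assert fm.adaptation_index == pytest.approx(0.5)

    def test_metrics_fail_independently(self):
        rec = _protocol_recording([150.0])
        trains = [_train(0, [160.0])]       # one spike: no ISI anywhere
        fm = firing_metrics(trains, rec)
        assert fm.max_freq_hz is None
        assert fm.fi_slope_hz_per_pa is None
        assert fm.adaptation_index is None
        assert set(fm.undefined_reasons) == {"max_freq", "fi_slope",
                                             "adaptation_index"}

    def test_fi_slope_matches_normal_equations_oracle(self, young_recording):
        rec, _ = young_recording
        trains = detect_all_spikes(rec)
        fm = firing_metrics(trains, rec)
        pts = [(rec.sweeps[t.sweep_index].stimulus.amplitude,
                t.instantaneous_freq_hz[0])
               for t in trains if t.instantaneous_freq_hz.size]
        x, y = map(np.array, zip(*pts))
        assert fm.fi_slope_hz_per_pa == pytest.approx(ols_slope(x, y),
                                                      rel=1e-9)


# ---------------------------------------------------------------------------
# AHP
# ---------------------------------------------------------------------------

def _recording_with_counts(counts, amps):
    """Flat sweeps plus fabricated spike trains with given in-step counts."""
    sweeps = [make_sweep(np.full(24001, -67.0), amplitude=a) for a in amps]
    trains = []
    for i, c in enumerate(counts):
        times = 160.0 + np.arange(c) * 10.0
        trains.append(_train(i, times))
    return make_recording(sweeps), trains


class TestAHP:
    def test_qualifying_sweep_is_first_with_twelve_spikes(self):
        rec, trains = _recording_with_counts(
            [5, 9, 11, 13, 18], [300.0, 350.0, 400.0, 450.0, 500.0])
        m = measure_ahp(rec, trains)
        assert m.current_pA == 450.0

    def test_flat_post_step_trace_has_zero_amplitude(self):
        rec, trains = _recording_with_counts([13], [450.0])
        m = measure_ahp(rec, trains)
        assert m.amplitude_mV == pytest.approx(0.0, abs=1e-12)

    def test_imposed_exponential_decay(self):
        # post-step deflection −4·e^(−t/150) mV: trough −4 at t=0,
        # baseline = mean over [600,700] ≈ −0.053 → amplitude ≈ 3.947
        dt = 0.05
        v = np.full(24001, -67.0)
        i_end = int(round(400.0 / dt))
        t = np.arange(24001 - i_end) * dt
        v[i_end:] += -4.0 * np.exp(-t / 150.0)
        sw = make_sweep(v, amplitude=450.0)
        rec = make_recording([sw])
        trains = [_train(0, 160.0 + np.arange(13) * 10.0)]
        m = measure_ahp(rec, trains)
        assert m.amplitude_mV == pytest.approx(3.946, abs=0.01)

    def test_no_qualifying_sweep_raises_with_reason(self):
        rec, trains = _recording_with_counts([5, 11], [300.0, 700.0])
        with pytest.raises(FeatureUndefined, match="insufficient_spiking"):
            measure_ahp(rec, trains)

    def test_short_post_step_epoch_is_an_error(self):
        sw = make_sweep(np.full(10000, -67.0), amplitude=450.0)  # 100 ms post
        rec = make_recording([sw])
        trains = [_train(0, 160.0 + np.arange(13) * 10.0)]
        with pytest.raises(ValidationError, match="post-step"):
            measure_ahp(rec, trains)

    def test_offset_invariance_and_scale_covariance(self):
        dt = 0.05
        base = np.full(24001, -67.0)
        i_end = int(round(400.0 / dt))
        t = np.arange(24001 - i_end) * dt
        deflect = -4.0 * np.exp(-t / 150.0)
        trains_proto = 160.0 + np.arange(13) * 10.0
        results = {}
        for k, offset in [(1.0, 0.0), (1.0, 12.5), (2.5, 0.0)]:
            v = base + offset
            v[i_end:] += k * deflect
            rec = make_recording([make_sweep(v, amplitude=450.0)])
            m = measure_ahp(rec, [_train(0, trains_proto)])
            results[(k, offset)] = m.amplitude_mV
        assert results[(1.0, 12.5)] == pytest.approx(results[(1.0, 0.0)],
                                                     abs=1e-9)
        assert results[(2.5, 0.0)] == pytest.approx(
            2.5 * results[(1.0, 0.0)], rel=1e-9)

    def test_recovery_against_noiseless_truth(self, young_recording):
        rec, gt = young_recording
        m = measure_ahp(rec, detect_all_spikes(rec))
        assert m.amplitude_mV == pytest.approx(gt.true_ahp_mV, abs=0.3)
        assert m.current_pA == gt.qualifying_amplitude_pA


# ---------------------------------------------------------------------------
# QC and aggregation
# ---------------------------------------------------------------------------

class TestQC:
    def test_insufficient_spiking(self):
        rec, trains = _recording_with_counts([5, 11], [300.0, 700.0])
        qc = qc_intrinsic(rec, trains)
        assert qc.excluded and qc.reasons == ["insufficient_spiking"]

    def test_clean_cell_passes(self, young_recording):
        rec, _ = young_recording
        qc = qc_intrinsic(rec, detect_all_spikes(rec))
        assert not qc.excluded

    def test_synaptic_bumps_in_ahp_epoch_exclude(self, young_recording):
        import copy
        rec, _ = young_recording
        rec2 = copy.deepcopy(rec)
        trains = detect_all_spikes(rec2)
        m = measure_ahp(rec2, trains)
        sw = rec2.sweeps[m.sweep_index]
        dt = sw.dt
        i_end = int(round(sw.stimulus.end / dt))
        # a ~50 Hz barrage of fast 3 mV EPSP-like bumps through the epoch
        t_bump = np.arange(0.0, 15.0, dt)
        bump = np.exp(-t_bump / 3.0) - np.exp(-t_bump / 0.5)
        bump *= 3.0 / bump.max()
        for k in range(35):
            j = i_end + int(round((10.0 + 20.0 * k) / dt))
            sw.samples[j:j + bump.size] += bump
        qc = qc_intrinsic(rec2, detect_all_spikes(rec2))
        assert qc.excluded
        assert qc.reasons == ["excessive_synaptic_input"]


class TestExtractAll:
    def test_missing_minus50_sweep_leaves_other_features_intact(self):
        from ephyskit.io import StepProtocol
        from ephyskit.simulate import NeuronParams, simulate_current_clamp
        proto = StepProtocol(amplitudes=tuple(float(a) for a
                                              in range(0, 701, 50)))
        rec, _ = simulate_current_clamp(NeuronParams(sigma=0.0), proto,
                                        seed=0)
        fs = extract_all(rec)
        assert fs.passive.input_resistance_mohm is None
        assert "rin_tau" in fs.passive.undefined_reasons
        assert fs.ap.threshold_mV is not None
        assert fs.ahp is not None

    def test_feature_table_has_one_row_per_cell(self, tmp_path):
        from ephyskit.io import read_feature_table, write_feature_table
        from ephyskit.simulate import simulate_current_clamp, young_like
        rows = []
        for s in range(10):
            rec, _ = simulate_current_clamp(young_like(), seed=s,
                                            ground_truth_ahp=False)
            rows.append(extract_all(rec).to_row())
        path = tmp_path / "cohort.csv"
        write_feature_table(rows, path)
        assert len(read_feature_table(path)) == 10
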