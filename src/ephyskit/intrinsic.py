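"""Current-clamp intrinsic-excitability feature extraction.

Implements the standard whole-cell feature battery for a current-step
protocol, with the qualification and exclusion rules used for aged CA1
recordings:

* spikes: upward 0 mV crossings, linearly interpolated, 1 ms merge guard;
* passive: resting potential (pre-stimulus mean), input resistance and
  membrane time constant from the −50 pA step (steady state = mean of the
  final 20 % of the step; τ = time to 63 % of the maximum voltage change);
* AP waveform (first elicited action potential): threshold at the maximum of
  d³V/dt³ just before the peak, amplitude = peak − threshold, half-width at
  threshold + amplitude/2;
* firing: maximum instantaneous frequency over all sweeps, F/I slope from
  the first instantaneous frequency vs current (positive points only),
  adaptation index (last/first instantaneous frequency) at 250 pA above the
  first spiking step;
* medium AHP: on the lowest-amplitude sweep with ≥ 12 in-step spikes
  (~50 Hz over 250 ms), baseline = mean over a 100 ms window starting
  600 ms after step end, trough = minimum within 175 ms after step end,
  amplitude = baseline − trough (positive = hyperpolarization);
* QC: cells are excluded if no sweep reaches 12 spikes, or if high-frequency
  residual power during the AHP epoch indicates excessive synaptic input.

Per-metric failures are carried as ``None`` + reason; one metric failing
never silently drops the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .io import CURRENT_CLAMP, Recording, StepProtocol, Sweep, ValidationError

__all__ = [
    "SpikeTrain",
    "PassiveProperties",
    "APWaveformMetrics",
    "FiringMetrics",
    "AHPMeasure",
    "IntrinsicQC",
    "IntrinsicFeatureSet",
    "AnalysisWindows",
    "detect_spikes",
    "resting_potential",
    "input_resistance",
    "membrane_time_constant",
    "ap_threshold",
    "ap_amplitude",
    "ap_half_width",
    "firing_metrics",
    "measure_ahp",
    "qc_intrinsic",
    "extract_all",
]


class FeatureUndefined(ValueError):
    """A feature's precondition failed (e.g. no spikes: threshold undefined)."""


@dataclass(frozen=True)
class AnalysisWindows:
    """Tunable analysis windows (ms unless noted); defaults are the standard
    protocol values."""

    ahp_baseline_start: float = 600.0   # after step end
    ahp_baseline_len: float = 100.0
    ahp_trough_len: float = 175.0       # after step end
    min_spikes: int = 12                # AHP qualification (≈50 Hz in 250 ms)
    spike_merge_ms: float = 1.0         # refractory merge guard
    threshold_search_ms: float = 2.0    # window before AP peak for d3V/dt3
    synaptic_hp_cutoff_hz: float = 20.0
    synaptic_rms_limit_mV: float = 0.5
    adaptation_offset_pA: float = 250.0


DEFAULT_WINDOWS = AnalysisWindows()


@dataclass
class SpikeTrain:
    """Spike times of one sweep and the derived instantaneous frequencies."""

    sweep_index: int
    times_ms: np.ndarray
    # 1/ISI per consecutive spike pair, Hz; empty if < 2 spikes
    instantaneous_freq_hz: np.ndarray

    @property
    def n_spikes(self) -> int:
        return self.times_ms.size

    def count_in(self, t0: float, t1: float) -> int:
        return int(np.sum((self.times_ms >= t0) & (self.times_ms < t1)))


@dataclass
class PassiveProperties:
    resting_potential_mV: float | None = None
    input_resistance_mohm: float | None = None
    membrane_tau_ms: float | None = None
    undefined_reasons: dict = field(default_factory=dict)


@dataclass
class APWaveformMetrics:
    threshold_mV: float | None = None
    amplitude_mV: float | None = None
    half_width_ms: float | None = None
    source_sweep: int | None = None
    undefined_reasons: dict = field(default_factory=dict)


@dataclass
class FiringMetrics:
    max_freq_hz: float | None = None
    fi_slope_hz_per_pa: float | None = None
    adaptation_index: float | None = None
    undefined_reasons: dict = field(default_factory=dict)


@dataclass
class AHPMeasure:
    sweep_index: int
    current_pA: float
    baseline_mV: float
    trough_mV: float
    amplitude_mV: float        # baseline − trough; positive = hyperpolarization


@dataclass
class IntrinsicQC:
    excluded: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValidationError("excluded: must match reasons non-empty")


@dataclass
class IntrinsicFeatureSet:
    cell_id: str
    group: str
    passive: PassiveProperties
    ap: APWaveformMetrics
    firing: FiringMetrics
    ahp: AHPMeasure | None
    qc: IntrinsicQC
    undefined_reasons: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten to one feature-table record."""
        return {
            "cell_id": self.cell_id,
            "group": self.group,
            "resting_mV": self.passive.resting_potential_mV,
            "rin_mohm": self.passive.input_resistance_mohm,
            "tau_ms": self.passive.membrane_tau_ms,
            "ap_threshold_mV": self.ap.threshold_mV,
            "ap_amplitude_mV": self.ap.amplitude_mV,
            "ap_half_width_ms": self.ap.half_width_ms,
            "max_freq_hz": self.firing.max_freq_hz,
            "fi_slope_hz_per_pa": self.firing.fi_slope_hz_per_pa,
            "adaptation_index": self.firing.adaptation_index,
            "ahp_mV": None if self.ahp is None else self.ahp.amplitude_mV,
            "ahp_current_pA": None if self.ahp is None else self.ahp.current_pA,
            "qc_excluded": self.qc.excluded,
            "qc_reasons": ";".join(self.qc.reasons),
        }


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def detect_spikes(sweep: Sweep, sweep_index: int = 0,
                  windows: AnalysisWindows = DEFAULT_WINDOWS) -> SpikeTrain:
    """One spike per upward 0 mV crossing, linearly interpolated.

    Crossings closer than the merge guard (default 1 ms) are collapsed to
    the first.
    """
    if sweep.mode != CURRENT_CLAMP:
        raise ValidationError("mode: spike detection needs a current-clamp sweep")
    v = sweep.samples
    below = v[:-1] < 0.0
    above = v[1:] >= 0.0
    idx = np.nonzero(below & above)[0]
    if idx.size:
        frac = (0.0 - v[idx]) / (v[idx + 1] - v[idx])
        times = (idx + frac) * sweep.dt
        keep = np.ones(times.size, dtype=bool)
        last = times[0]
        for i in range(1, times.size):
            if times[i] - last < windows.spike_merge_ms:
                keep[i] = False
            else:
                last = times[i]
        times = times[keep]
    else:
        times = np.empty(0)
    isi = np.diff(times)
    freq = 1000.0 / isi if isi.size else np.empty(0)
    return SpikeTrain(sweep_index=sweep_index, times_ms=times,
                      instantaneous_freq_hz=freq)


def detect_all_spikes(recording: Recording,
                      windows: AnalysisWindows = DEFAULT_WINDOWS
                      ) -> list[SpikeTrain]:
    return [detect_spikes(sw, i, windows)
            for i, sw in enumerate(recording.sweeps)]


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------

def resting_potential(sweep: Sweep, *, min_len_ms: float = 100.0) -> float:
    """Mean voltage of the pre-stimulus segment (must be ≥ 100 ms)."""
    onset = sweep.stimulus.onset
    if onset < min_len_ms:
        raise FeatureUndefined(
            f"resting potential: pre-stimulus segment {onset:.0f} ms "
            f"< {min_len_ms:.0f} ms")
    n0 = int(round(onset / sweep.dt))
    return float(np.mean(sweep.samples[:n0]))


def _baseline_and_steady(sweep: Sweep) -> tuple[float, float]:
    """Pre-step baseline mean and steady-state mean (final 20 % of the step)."""
    stim = sweep.stimulus
    dt = sweep.dt
    i_on = int(round(stim.onset / dt))
    i_off = int(round(stim.end / dt))
    i_ss = int(round((stim.end - 0.2 * stim.duration) / dt))
    baseline = float(np.mean(sweep.samples[:i_on]))
    steady = float(np.mean(sweep.samples[i_ss:i_off]))
    return baseline, steady


def input_resistance(sweep: Sweep) -> float:
    """ΔV(steady state) / I at the −50 pA step, in MΩ."""
    import warnings

    amp = sweep.stimulus.amplitude
    if abs(amp + 50.0) > 1e-6:
        raise FeatureUndefined(
            f"input resistance: needs the -50 pA sweep, got {amp} pA")
    baseline, steady = _baseline_and_steady(sweep)
    dv = steady - baseline
    if dv == 0.0:
        warnings.warn("input resistance: zero deflection (non-physiological)",
                      stacklevel=2)
        return 0.0
    # mV / pA = GΩ; × 1000 → MΩ
    return float(dv / amp * 1000.0)


def membrane_time_constant(sweep: Sweep) -> float:
    """Time to reach 63 % of the maximum (steady-state) voltage change of the
    −50 pA step, linearly interpolated from step onset."""
    amp = sweep.stimulus.amplitude
    if abs(amp + 50.0) > 1e-6:
        raise FeatureUndefined(
            f"membrane tau: needs the -50 pA sweep, got {amp} pA")
    baseline, steady = _baseline_and_steady(sweep)
    dv = steady - baseline
    if dv == 0.0:
        raise FeatureUndefined("membrane tau: maximum voltage change is zero")
    dt = sweep.dt
    i_on = int(round(sweep.stimulus.onset / dt))
    i_off = int(round(sweep.stimulus.end / dt))
    target = baseline + 0.63 * dv
    seg = sweep.samples[i_on:i_off]
    rel = (seg - target) * np.sign(dv)
    hit = np.nonzero(rel >= 0.0)[0]
    if hit.size == 0:
        raise FeatureUndefined("membrane tau: 63% level never reached in step")
    k = int(hit[0])
    if k == 0:
        return 0.0
    frac = rel[k - 1] / (rel[k - 1] - rel[k])
    return float((k - 1 + frac) * dt)


# ---------------------------------------------------------------------------
# AP waveform (first elicited action potential)
# ---------------------------------------------------------------------------

def _smooth5(x: np.ndarray) -> np.ndarray:
    return uniform_filter1d(x, size=5, mode="nearest")


def _first_ap(recording: Recording, trains: Sequence[SpikeTrain]
              ) -> tuple[Sweep, SpikeTrain, int]:
    """The first spike of the lowest-amplitude sweep that spikes."""
    order = np.argsort([sw.stimulus.amplitude for sw in recording.sweeps])
    for j in order:
        if trains[j].n_spikes > 0:
            return recording.sweeps[j], trains[j], int(j)
    raise FeatureUndefined("threshold undefined: no spikes in any sweep")


def _ap_peak_index(sweep: Sweep, spike_time_ms: float) -> int:
    """Index of the AP peak: maximum within 2 ms after the 0 mV crossing."""
    dt = sweep.dt
    i0 = int(spike_time_ms / dt)
    i1 = min(i0 + int(round(2.0 / dt)) + 1, sweep.n)
    return i0 + int(np.argmax(sweep.samples[i0:i1]))


def ap_threshold(sweep: Sweep, train: SpikeTrain,
                 windows: AnalysisWindows = DEFAULT_WINDOWS,
                 smooth: bool = True) -> float:
    """Voltage at the maximal third derivative just before the first AP peak.

    d³V/dt³ by repeated central differences, each stage lightly smoothed
    (5-point moving average) to keep the raw-trace estimate usable at
    recording noise; ``smooth=False`` gives the plain finite-difference
    estimate.
    """
    if train.n_spikes == 0:
        raise FeatureUndefined("threshold undefined: sweep has no spikes")
    dt = sweep.dt
    peak = _ap_peak_index(sweep, train.times_ms[0])
    i0 = max(peak - int(round(windows.threshold_search_ms / dt)), 1)
    # stop 3 samples short of the peak: the triple central-difference
    # stencil spans ±3 samples, and the peak's own curvature break would
    # otherwise dominate the search
    hi = peak - 3
    d = sweep.samples
    for _ in range(3):
        d = np.gradient(d, dt)
        if smooth:
            d = _smooth5(d)
    if i0 >= hi:
        raise FeatureUndefined("threshold undefined: empty search window")
    k = i0 + int(np.argmax(d[i0:hi]))
    return float(sweep.samples[k])


def ap_amplitude(sweep: Sweep, train: SpikeTrain,
                 threshold_mV: float) -> float:
    """Peak voltage of the first AP minus the spike threshold."""
    if train.n_spikes == 0:
        raise FeatureUndefined("amplitude undefined: sweep has no spikes")
    peak = _ap_peak_index(sweep, train.times_ms[0])
    return float(sweep.samples[peak] - threshold_mV)


def ap_half_width(sweep: Sweep, train: SpikeTrain, threshold_mV: float,
                  amplitude_mV: float, *, max_fall_ms: float = 10.0) -> float:
    """Duration of the first AP at half amplitude (level = threshold +
    amplitude/2), crossings linearly interpolated."""
    if train.n_spikes == 0:
        raise FeatureUndefined("half-width undefined: sweep has no spikes")
    dt = sweep.dt
    v = sweep.samples
    peak = _ap_peak_index(sweep, train.times_ms[0])
    level = threshold_mV + amplitude_mV / 2.0
    # upward crossing: scan back from the peak
    i = peak
    while i > 0 and v[i - 1] >= level:
        i -= 1
    if i == 0:
        raise FeatureUndefined("half-width undefined: no upward crossing")
    t_up = (i - 1 + (level - v[i - 1]) / (v[i] - v[i - 1])) * dt
    # downward crossing: scan forward from the peak
    j = peak
    j_max = min(peak + int(round(max_fall_ms / dt)), v.size - 1)
    while j < j_max and v[j + 1] > level:
        j += 1
    if j == j_max:
        raise FeatureUndefined(
            f"half-width undefined: no downward crossing within "
            f"{max_fall_ms} ms of peak")
    t_down = (j + (v[j] - level) / (v[j] - v[j + 1])) * dt
    return float(t_down - t_up)


# ---------------------------------------------------------------------------
# firing metrics
# ---------------------------------------------------------------------------

def firing_metrics(trains: Sequence[SpikeTrain], recording: Recording,
                   windows: AnalysisWindows = DEFAULT_WINDOWS) -> FiringMetrics:
    """Max instantaneous frequency, F/I slope, and adaptation index.

    Each metric reports its own undefined reason without failing the others.
    """
    out = FiringMetrics()
    amps = np.array([sw.stimulus.amplitude for sw in recording.sweeps])

    all_freqs = np.concatenate(
        [t.instantaneous_freq_hz for t in trains]) if trains else np.empty(0)
    if all_freqs.size:
        out.max_freq_hz = float(np.max(all_freqs))
    else:
        out.undefined_reasons["max_freq"] = "no sweep with >= 2 spikes"

    # F/I: first instantaneous frequency vs current, positive points only
    pts = [(amps[t.sweep_index], t.instantaneous_freq_hz[0])
           for t in trains if t.instantaneous_freq_hz.size > 0]
    if len(pts) >= 2:
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        out.fi_slope_hz_per_pa = float(np.polyfit(x, y, 1)[0])
    else:
        out.undefined_reasons["fi_slope"] = (
            f"needs >= 2 positive F/I points, have {len(pts)}")

    # adaptation index at (first spiking step + 250 pA), nearest grid step
    spiking = [t.sweep_index for t in trains if t.n_spikes > 0]
    if not spiking:
        out.undefined_reasons["adaptation_index"] = "no spiking sweep"
        return out
    first_amp = float(np.min(amps[spiking]))
    target = first_amp + windows.adaptation_offset_pA
    j = int(np.argmin(np.abs(amps - target)))
    tr = trains[j]
    if tr.instantaneous_freq_hz.size < 1:
        out.undefined_reasons["adaptation_index"] = (
            f"sweep at {amps[j]:.0f} pA has < 2 spikes")
    else:
        f = tr.instantaneous_freq_hz
        out.adaptation_index = float(f[-1] / f[0])
    return out


# ---------------------------------------------------------------------------
# AHP
# ---------------------------------------------------------------------------

def measure_ahp(recording: Recording, trains: Sequence[SpikeTrain],
                windows: AnalysisWindows = DEFAULT_WINDOWS) -> AHPMeasure:
    """Medium AHP on the lowest-amplitude sweep with ≥ 12 in-step spikes.

    baseline = mean over [end+600, end+700) ms; trough = min over
    [end, end+175) ms; amplitude = baseline − trough.
    """
    order = np.argsort([sw.stimulus.amplitude for sw in recording.sweeps])
    qual = None
    for j in order:
        sw = recording.sweeps[j]
        stim = sw.stimulus
        if trains[j].count_in(stim.onset, stim.end) >= windows.min_spikes:
            qual = int(j)
            break
    if qual is None:
        raise FeatureUndefined(
            f"AHP undefined: no sweep with >= {windows.min_spikes} spikes "
            "(insufficient_spiking)")
    sw = recording.sweeps[qual]
    end = sw.stimulus.end
    need = windows.ahp_baseline_start + windows.ahp_baseline_len
    if sw.post_step_span() < need:
        raise ValidationError(
            f"sweep {qual}: only {sw.post_step_span():.0f} ms post-step; "
            f"AHP windows need {need:.0f} ms")
    dt = sw.dt
    b0 = int(round((end + windows.ahp_baseline_start) / dt))
    b1 = int(round((end + windows.ahp_baseline_start
                    + windows.ahp_baseline_len) / dt))
    t0 = int(round(end / dt))
    t1 = int(round((end + windows.ahp_trough_len) / dt))
    baseline = float(np.mean(sw.samples[b0:b1]))
    trough = float(np.min(sw.samples[t0:t1]))
    return AHPMeasure(sweep_index=qual,
                      current_pA=sw.stimulus.amplitude,
                      baseline_mV=baseline, trough_mV=trough,
                      amplitude_mV=baseline - trough)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _highpass_rms(x: np.ndarray, dt_ms: float, cutoff_hz: float) -> float:
    fs = 1000.0 / dt_ms
    sos = butter(2, cutoff_hz, btype="highpass", fs=fs, output="sos")
    resid = sosfiltfilt(sos, x)
    return float(np.sqrt(np.mean(resid ** 2)))


def qc_intrinsic(recording: Recording, trains: Sequence[SpikeTrain],
                 windows: AnalysisWindows = DEFAULT_WINDOWS) -> IntrinsicQC:
    """Exclusion rules: no sweep reaches 12 in-step spikes, or the AHP epoch
    carries excessive synaptic input (high-pass residual RMS above limit)."""
    reasons: list[str] = []
    counts = [t.count_in(sw.stimulus.onset, sw.stimulus.end)
              for t, sw in zip(trains, recording.sweeps)]
    qual_idx = None
    order = np.argsort([sw.stimulus.amplitude for sw in recording.sweeps])
    for j in order:
        if counts[j] >= windows.min_spikes:
            qual_idx = int(j)
            break
    if qual_idx is None:
        reasons.append("insufficient_spiking")
    else:
        sw = recording.sweeps[qual_idx]
        end = sw.stimulus.end
        span = windows.ahp_baseline_start + windows.ahp_baseline_len
        i0 = int(round(end / sw.dt))
        i1 = min(int(round((end + span) / sw.dt)), sw.n)
        rms = _highpass_rms(sw.samples[i0:i1], sw.dt,
                            windows.synaptic_hp_cutoff_hz)
        if rms > windows.synaptic_rms_limit_mV:
            reasons.append("excessive_synaptic_input")
    return IntrinsicQC(excluded=bool(reasons), reasons=reasons)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def extract_all(recording: Recording,
                windows: AnalysisWindows = DEFAULT_WINDOWS
                ) -> IntrinsicFeatureSet:
    """Run the full intrinsic battery; undefined metrics are carried with
    their reasons, and excluded cells are flagged but still reported."""
    if recording.mode != CURRENT_CLAMP:
        raise ValidationError(
            f"mode: extract_all needs current clamp (cell {recording.cell_id})")
    trains = detect_all_spikes(recording, windows)

    passive = PassiveProperties()
    try:
        passive.resting_potential_mV = resting_potential(recording.sweeps[0])
    except FeatureUndefined as e:
        passive.undefined_reasons["resting"] = str(e)
    try:
        sw50 = recording.sweep_at(-50.0)
        passive.input_resistance_mohm = input_resistance(sw50)
        passive.membrane_tau_ms = membrane_time_constant(sw50)
    except (ValidationError, FeatureUndefined) as e:
        passive.undefined_reasons["rin_tau"] = str(e)

    ap = APWaveformMetrics()
    try:
        sw, tr, j = _first_ap(recording, trains)
        ap.source_sweep = j
        ap.threshold_mV = ap_threshold(sw, tr, windows)
        ap.amplitude_mV = ap_amplitude(sw, tr, ap.threshold_mV)
        ap.half_width_ms = ap_half_width(sw, tr, ap.threshold_mV,
                                         ap.amplitude_mV)
    except FeatureUndefined as e:
        ap.undefined_reasons["ap"] = str(e)

    firing = firing_metrics(trains, recording, windows)

    ahp = None
    undefined: dict = {}
    try:
        ahp = measure_ahp(recording, trains, windows)
    except FeatureUndefined as e:
        undefined["ahp"] = str(e)

    qc = qc_intrinsic(recording, trains, windows)
    return IntrinsicFeatureSet(cell_id=recording.cell_id,
                               group=recording.group,
                               passive=passive, ap=ap, firing=firing,
                               ahp=ahp, qc=qc, undefined_reasons=undefined)
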