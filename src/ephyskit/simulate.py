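"""Synthetic recordings and cohort tables with known ground truth.

Every downstream stage of the package (feature extraction, event detection,
statistics) is testable against these generators without any external data.

Current clamp
    An exponential-integrate-and-fire neuron with a spike-triggered AHP
    (afterhyperpolarization) potassium-like conductance::

        C dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_T)/Δ_T)
                  + I(t) - w - g_AHP(t) (V - E_K) + noise
        τ_w  dw/dt     = a (V - E_L) - w
        τ_AHP dg_AHP/dt = -g_AHP ;   g_AHP += b_AHP at each spike

    When V crosses the cutoff ``V_cut`` a stereotyped 2 ms action-potential
    waveform peaking at +30 mV is pasted into the trace (so that a 0 mV
    upward-crossing spike detector has something to cross) and V resets.
    The model is an emulation chosen to expose exactly the quantities the
    extractor must recover — input resistance 1/g_L, time constant C/g_L,
    a threshold-like spike onset, and a tunable AHP — not a claim about CA1
    biophysics.

Voltage clamp
    A homogeneous Poisson train of inward (negative) synaptic-current events
    with log-normal amplitudes and a difference-of-exponentials kernel, plus
    Gaussian baseline noise, linear baseline drift and an access-resistance
    trajectory, emulating a 4 min sEPSC recording at −75 mV.

Cohorts
    Per-subject Gaussian feature tables with stated group means/SDs and
    Gaussian-copula correlation links, emulating per-animal marker/behavior
    tables.

Determinism: every generator takes an explicit integer seed; identical seeds
give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .io import (CURRENT_CLAMP, VOLTAGE_CLAMP, Recording, StepProtocol, Sweep,
                 StimulusStep, ValidationError, default_step_protocol)

__all__ = [
    "NeuronParams",
    "EventTrainParams",
    "CohortSpec",
    "GroundTruth",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "simulate_cohort",
    "young_like",
    "old_like",
    "ahp_calibration_curve",
    "epsc_kernel",
]

#: integration / sampling interval, ms (20 kHz)
DT_MS = 0.05
#: pasted AP: rise 0.5 ms to +30 mV, fall 1.5 ms to the reset potential
AP_PEAK_MV = 30.0
AP_RISE_MS = 0.5
AP_FALL_MS = 1.5


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the integrate-and-fire emulation (units in comments)."""

    g_L: float = 6.667        # leak conductance, nS  (Rin = 1000/g_L MΩ)
    C: float = 100.0          # capacitance, pF        (τ_m = C/g_L ms)
    E_L: float = -67.0        # resting potential, mV
    V_T: float = -50.0        # spike-initiation threshold, mV
    Delta_T: float = 2.0      # slope factor, mV
    V_reset: float = -60.0    # post-spike reset, mV
    V_cut: float = -30.0      # integration cutoff that triggers the paste, mV
    b_AHP: float = 0.15       # AHP conductance increment per spike, nS
    tau_AHP: float = 150.0    # AHP conductance decay, ms
    E_K: float = -90.0        # AHP reversal, mV
    a: float = 0.0            # subthreshold adaptation coupling, nS
    tau_w: float = 100.0      # adaptation decay, ms
    sigma: float = 0.1        # membrane noise (stationary RMS), mV

    def __post_init__(self) -> None:
        for name in ("g_L", "C", "tau_AHP", "tau_w"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be > 0")
        if not (self.E_K < self.E_L < self.V_T < self.V_cut):
            raise ValidationError(
                "potentials: require E_K < E_L < V_T < V_cut "
                f"(got {self.E_K}, {self.E_L}, {self.V_T}, {self.V_cut})")
        if self.b_AHP < 0 or self.sigma < 0:
            raise ValidationError("b_AHP/sigma: must be >= 0")

    @property
    def rin_mohm(self) -> float:
        """Noiseless input resistance implied by the leak, MΩ."""
        return 1000.0 / (self.g_L + self.a)

    @property
    def tau_ms(self) -> float:
        """Noiseless membrane time constant, ms."""
        return self.C / (self.g_L + self.a)


def young_like(**overrides) -> NeuronParams:
    """Preset with a small spike-triggered AHP (~2 mV measured amplitude).

    The magnitude is synthetic: chosen so that the young/old preset pair is
    separated by ~2 mV of AHP, the scale of group effect the statistics layer
    must detect at realistic cohort sizes.
    """
    return NeuronParams(b_AHP=B_AHP_YOUNG, **overrides)


def old_like(**overrides) -> NeuronParams:
    """Preset with a large spike-triggered AHP (~4 mV measured amplitude)."""
    return NeuronParams(b_AHP=B_AHP_OLD, **overrides)


# b_AHP values giving ~2.0 mV (young) and ~4.0 mV (old) noiseless AHP under
# the default parameters and protocol; see ahp_calibration_curve.  The
# curve has small jumps where the lowest qualifying (>=12 spike) sweep index
# changes, so preset values sit on its locally monotone stretches.
B_AHP_YOUNG = 0.15
B_AHP_OLD = 0.29
#: approximate local slope of AHP amplitude vs b_AHP near the presets, mV/nS
AHP_PER_B_SLOPE = 15.6


@dataclass(frozen=True)
class EventTrainParams:
    """Parameters of the synthetic voltage-clamp sEPSC recording."""

    rate_hz: float = 2.0          # Poisson event rate, Hz
    amp_median_pA: float = 20.0   # log-normal amplitude median, pA
    amp_shape: float = 0.3        # log-normal shape (sigma of log)
    tau_r_ms: float = 0.7         # kernel rise time constant, ms
    tau_d_ms: float = 5.0         # kernel decay time constant, ms
    duration_s: float = 240.0     # recording length (4 min), s
    noise_rms_pA: float = 2.0     # Gaussian baseline noise RMS, pA
    drift_pA: float = 0.0         # linear baseline drift over the recording
    ra_start_mohm: float = 12.0   # access resistance at t=0, MΩ
    ra_end_mohm: float = 12.0     # access resistance at the end, MΩ
    dt_ms: float = DT_MS

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValidationError("rate_hz: must be >= 0")
        if not (self.tau_d_ms > self.tau_r_ms > 0):
            raise ValidationError("tau: require tau_d > tau_r > 0")
        if self.duration_s <= 0:
            raise ValidationError("duration_s: must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Group structure of a synthetic per-subject measurement table.

    ``groups`` maps label -> (n, {feature: mean}, {feature: sd});
    ``correlations`` lists (feature_a, feature_b, target_pearson_r) links
    realized through a Gaussian copula.
    """

    groups: Sequence[tuple[str, int, Mapping[str, float], Mapping[str, float]]]
    correlations: Sequence[tuple[str, str, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n, means, sds in self.groups:
            if n < 2:
                raise ValidationError(f"group {label}: n must be >= 2")
            for f, sd in sds.items():
                if sd < 0:
                    raise ValidationError(f"group {label}/{f}: sd must be >= 0")
        for fa, fb, r in self.correlations:
            if abs(r) > 1:
                raise ValidationError(f"correlation {fa}~{fb}: |r| must be <= 1")


@dataclass
class GroundTruth:
    """What the generator actually put into a recording."""

    spike_times_ms: list[np.ndarray] | None = None   # per sweep
    spike_counts: np.ndarray | None = None           # in-step spikes per sweep
    true_rin_mohm: float | None = None
    true_tau_ms: float | None = None
    true_ahp_mV: float | None = None                 # from noiseless replicate
    qualifying_amplitude_pA: float | None = None
    event_times_ms: np.ndarray | None = None         # voltage clamp
    event_amplitudes_pA: np.ndarray | None = None

    def to_jsonable(self) -> dict:
        def arr(x):
            return None if x is None else np.asarray(x).tolist()
        return {
            "spike_times_ms": (None if self.spike_times_ms is None
                               else [t.tolist() for t in self.spike_times_ms]),
            "spike_counts": arr(self.spike_counts),
            "true_rin_mohm": self.true_rin_mohm,
            "true_tau_ms": self.true_tau_ms,
            "true_ahp_mV": self.true_ahp_mV,
            "qualifying_amplitude_pA": self.qualifying_amplitude_pA,
            "event_times_ms": arr(self.event_times_ms),
            "event_amplitudes_pA": arr(self.event_amplitudes_pA),
        }


# ---------------------------------------------------------------------------
# current clamp
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _eif_sweep(n, dt, onset_idx, offset_idx, i_hold, i_step,
               gL, C, EL, VT, DT_slope, Vreset, Vcut, bAHP, tauAHP, EK,
               a, tauw, sigma_step, noise):  # pragma: no cover - jitted
    """Euler integration of one sweep; returns (V, spike_times, n_spikes).

    ``noise`` is a pre-drawn standard-normal array (one entry per sample).
    Spike times are the exact 0 mV upward crossings of the pasted linear AP
    rise, i.e. the generator's own spike log.
    """
    V = np.empty(n)
    v = EL
    w = 0.0
    gahp = 0.0
    V[0] = v
    rise_n = int(AP_RISE_MS / dt + 0.5)
    fall_n = int(AP_FALL_MS / dt + 0.5)
    max_spikes = 400
    spikes = np.empty(max_spikes)
    ns = 0
    i = 0
    while i < n - 1:
        I = i_hold
        if onset_idx <= i < offset_idx:
            I = i_hold + i_step
        ex = (v - VT) / DT_slope
        if ex > 20.0:
            ex = 20.0
        # exp term is < 0.02 pA when 7 slope factors below threshold
        expterm = gL * DT_slope * math.exp(ex) if ex > -7.0 else 0.0
        dv = (dt / C) * (-gL * (v - EL) + expterm
                         + I - w - gahp * (v - EK))
        if sigma_step > 0.0:
            dv += sigma_step * noise[i]
        w += dt * (a * (v - EL) - w) / tauw
        gahp -= dt * gahp / tauAHP
        v = v + dv
        if v >= Vcut:
            # paste stereotyped AP: linear rise Vcut -> +30, fall -> Vreset
            start = i + 1
            if ns < max_spikes:
                frac = (0.0 - Vcut) / (AP_PEAK_MV - Vcut)
                spikes[ns] = (start + frac * rise_n) * dt
                ns += 1
            for k in range(rise_n + 1):
                idx = start + k
                if idx < n:
                    V[idx] = Vcut + (AP_PEAK_MV - Vcut) * k / rise_n
            for k in range(1, fall_n + 1):
                idx = start + rise_n + k
                if idx < n:
                    V[idx] = AP_PEAK_MV + (Vreset - AP_PEAK_MV) * k / fall_n
            gahp += bAHP
            decay = math.exp(-(rise_n + fall_n) * dt / tauAHP)
            gahp *= decay
            w *= math.exp(-(rise_n + fall_n) * dt / tauw)
            i = start + rise_n + fall_n
            v = Vreset
            if i < n:
                V[i] = v
            continue
        i += 1
        V[i] = v
    return V, spikes[:ns], ns


def _window_mean(V: np.ndarray, dt: float, t0: float, t1: float) -> float:
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    return float(np.mean(V[i0:i1]))


def _window_min(V: np.ndarray, dt: float, t0: float, t1: float) -> float:
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    return float(np.min(V[i0:i1]))


def _ahp_from_sweep(V: np.ndarray, dt: float, step_end_ms: float) -> float:
    """AHP amplitude (baseline − trough, mV) with the standard windows:
    baseline = mean over [end+600, end+700) ms, trough = min over
    [end, end+175) ms."""
    baseline = _window_mean(V, dt, step_end_ms + 600.0, step_end_ms + 700.0)
    trough = _window_min(V, dt, step_end_ms, step_end_ms + 175.0)
    return baseline - trough


def simulate_current_clamp(
    params: NeuronParams,
    protocol: StepProtocol | None = None,
    seed: int = 0,
    *,
    onset_ms: float = 150.0,
    post_ms: float = 800.0,
    min_spikes: int = 12,
    ground_truth_ahp: bool = True,
) -> tuple[Recording, GroundTruth]:
    """Simulate one cell's full current-step protocol.

    One sweep per protocol amplitude at dt = 0.05 ms, each with ``onset_ms``
    of pre-step baseline and ``post_ms`` recorded after step termination
    (the AHP baseline window needs 700 ms).  Ground truth carries the
    integrator's own spike log and the AHP amplitude measured on a noiseless
    replicate of the same cell (skipped when ``ground_truth_ahp`` is False,
    which halves the cost for large cohort studies that only need the noisy
    recording).
    """
    protocol = protocol or default_step_protocol()
    dt = DT_MS
    n = int(round((onset_ms + protocol.step_duration + post_ms) / dt)) + 1
    onset_idx = int(round(onset_ms / dt))
    offset_idx = int(round((onset_ms + protocol.step_duration) / dt))
    sigma_step = params.sigma * math.sqrt(2.0 * dt * params.g_L / params.C)
    seeds = np.random.SeedSequence(seed).generate_state(len(protocol.amplitudes))

    sweeps: list[Sweep] = []
    spike_times: list[np.ndarray] = []
    counts = np.zeros(len(protocol.amplitudes), dtype=int)
    step_end = onset_ms + protocol.step_duration
    empty_noise = np.empty(0, dtype=np.float32)
    for j, amp in enumerate(protocol.amplitudes):
        noise = (np.random.default_rng(seeds[j])
                 .standard_normal(n, dtype=np.float32)
                 if sigma_step > 0 else empty_noise)
        V, st, ns = _eif_sweep(
            n, dt, onset_idx, offset_idx, 0.0, amp,
            params.g_L, params.C, params.E_L, params.V_T, params.Delta_T,
            params.V_reset, params.V_cut, params.b_AHP, params.tau_AHP,
            params.E_K, params.a, params.tau_w, sigma_step, noise)
        stim = StimulusStep(amplitude=amp, onset=onset_ms,
                            duration=protocol.step_duration)
        sweeps.append(Sweep(samples=V, dt=dt, stimulus=stim,
                            mode=CURRENT_CLAMP))
        spike_times.append(np.asarray(st))
        counts[j] = int(np.sum((st >= onset_ms) & (st < step_end)))

    gt = GroundTruth(spike_times_ms=spike_times, spike_counts=counts,
                     true_rin_mohm=params.rin_mohm, true_tau_ms=params.tau_ms)

    # noiseless replicate for the AHP ground truth
    if params.sigma > 0:
        if ground_truth_ahp:
            _, gt_quiet = simulate_current_clamp(
                replace(params, sigma=0.0), protocol, seed,
                onset_ms=onset_ms, post_ms=post_ms, min_spikes=min_spikes)
            gt.true_ahp_mV = gt_quiet.true_ahp_mV
            gt.qualifying_amplitude_pA = gt_quiet.qualifying_amplitude_pA
    else:
        qual = np.nonzero(counts >= min_spikes)[0]
        if qual.size:
            j = int(qual[0])
            gt.true_ahp_mV = _ahp_from_sweep(sweeps[j].samples, dt, step_end)
            gt.qualifying_amplitude_pA = protocol.amplitudes[j]

    rec = Recording(cell_id=f"sim-cc-{seed}", animal_id=f"sim-animal-{seed}",
                    group="synthetic", sweeps=sweeps)
    return rec, gt


def ahp_calibration_curve(
    b_grid: Sequence[float],
    params: NeuronParams | None = None,
    protocol: StepProtocol | None = None,
) -> np.ndarray:
    """Measured (noiseless) AHP amplitude for each b_AHP value in ``b_grid``.

    Used to place per-neuron b_AHP values so that a cohort hits target AHP
    means/SDs in millivolt units.  Monotone increasing in b_AHP.
    """
    base = params or NeuronParams()
    out = np.empty(len(b_grid))
    for i, b in enumerate(b_grid):
        p = replace(base, b_AHP=float(b), sigma=0.0)
        _, gt = simulate_current_clamp(p, protocol, seed=0)
        out[i] = np.nan if gt.true_ahp_mV is None else gt.true_ahp_mV
    return out


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def epsc_kernel(tau_r_ms: float = 0.7, tau_d_ms: float = 5.0,
                dt_ms: float = DT_MS, support_tau: float = 8.0) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel (positive peak 1).

    Support runs to ``support_tau`` decay time constants.
    """
    if not tau_d_ms > tau_r_ms > 0:
        raise ValidationError("tau: require tau_d > tau_r > 0")
    t = np.arange(0.0, support_tau * tau_d_ms + dt_ms / 2, dt_ms)
    k = np.exp(-t / tau_d_ms) - np.exp(-t / tau_r_ms)
    peak = k.max()
    if peak <= 0:
        raise ValidationError("kernel: zero peak")
    return k / peak


def simulate_voltage_clamp(
    params: EventTrainParams, seed: int = 0
) -> tuple[Recording, GroundTruth]:
    """Simulate a continuous voltage-clamp trace of inward sEPSCs.

    trace = Σ_i −A_i · k(t − t_i) + Gaussian noise + linear drift, with k the
    unit-peak kernel and t_i homogeneous Poisson of the given rate.  Inward
    events are negative deflections; ground-truth amplitudes are stored as
    positive magnitudes.
    """
    rng = np.random.default_rng(seed)
    dt = params.dt_ms
    n = int(round(params.duration_s * 1000.0 / dt))
    n_events = rng.poisson(params.rate_hz * params.duration_s)
    t_events = np.sort(rng.uniform(0.0, params.duration_s * 1000.0, n_events))
    amps = params.amp_median_pA * np.exp(
        params.amp_shape * rng.standard_normal(n_events))

    trace = np.zeros(n)
    kernel = epsc_kernel(params.tau_r_ms, params.tau_d_ms, dt)
    L = kernel.size
    for t0, A in zip(t_events, amps):
        i0 = int(round(t0 / dt))
        j1 = min(i0 + L, n)
        if i0 < n:
            trace[i0:j1] -= A * kernel[: j1 - i0]
    if params.noise_rms_pA > 0:
        trace += rng.normal(0.0, params.noise_rms_pA, n)
    if params.drift_pA != 0.0:
        trace += np.linspace(0.0, params.drift_pA, n)

    stim = StimulusStep(amplitude=0.0, onset=0.0,
                        duration=params.duration_s * 1000.0)
    sweep = Sweep(samples=trace, dt=dt, stimulus=stim, mode=VOLTAGE_CLAMP)
    ra_t = np.arange(0.0, params.duration_s + 1e-9, 10.0)
    ra = np.interp(ra_t, [0.0, params.duration_s],
                   [params.ra_start_mohm, params.ra_end_mohm])
    rec = Recording(cell_id=f"sim-vc-{seed}", animal_id=f"sim-animal-{seed}",
                    group="synthetic", sweeps=[sweep],
                    holding_potential=-75.0,
                    access_resistance_series=np.column_stack([ra_t, ra]))
    gt = GroundTruth(event_times_ms=t_events, event_amplitudes_pA=amps)
    return rec, gt


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec):
    """Per-subject measurement table with stated group effects.

    Features are Gaussian at each group's mean/SD; correlation links are
    realized by a shared multivariate-normal copula (so for Gaussian margins
    the target Pearson r is hit in expectation).  Returns a pandas DataFrame
    with columns ``subject``, ``group``, then one column per feature.
    """
    import pandas as pd

    features: list[str] = []
    for _, _, means, sds in spec.groups:
        for f in means:
            if f not in features:
                features.append(f)
        if set(means) != set(sds):
            raise ValidationError("groups: means and sds must share features")
    p = len(features)
    corr = np.eye(p)
    for fa, fb, r in spec.correlations:
        for f in (fa, fb):
            if f not in features:
                raise ValidationError(f"correlations: unknown feature {f!r}")
        ia, ib = features.index(fa), features.index(fb)
        corr[ia, ib] = corr[ib, ia] = r
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-9:
        raise ValidationError(
            f"correlations: matrix not positive semi-definite "
            f"(min eigenvalue {vals.min():.3g})")
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))

    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for label, n, means, sds in spec.groups:
        z = rng.standard_normal((n, p)) @ factor.T
        for i in range(n):
            row = {"subject": f"s{sid:03d}", "group": label}
            for j, f in enumerate(features):
                row[f] = means[f] + sds[f] * z[i, j]
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows, columns=["subject", "group", *features])
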