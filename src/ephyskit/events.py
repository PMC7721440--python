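"""Spontaneous EPSC detection by scaled-template matching, with recording QC.

The detector is the classic sliding least-squares template fit: at every lag
the template is fitted to the trace with a free scale and offset, and the
detection criterion is the fitted scale divided by its standard error.
Local maxima of the criterion above threshold, separated by at least the
template's rise+decay span, become events.  Inward (negative) deflections
fit a negated unit-peak kernel, so fitted scales and reported amplitudes are
positive magnitudes in pA.

Recording-quality gates (all must pass for a cell to be analyzable):

* access resistance never above 30 MΩ;
* baseline stable: |median of last 10 s − median of first 10 s| < 50 pA;
* baseline noise below 8 pA RMS (robust MAD estimate on the high-pass
  residual, so the events themselves do not inflate it).

Summaries follow the first-250-events rule: if more than 250 events are
detected, only the first 250 are analyzed and the analyzed duration is the
time of the 250th event; the frequency denominator is the span actually
scanned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import fftconvolve, find_peaks

from .io import VOLTAGE_CLAMP, Recording, Sweep, ValidationError
from .simulate import epsc_kernel

__all__ = [
    "Template",
    "DetectedEvent",
    "VCQC",
    "EventSeriesSummary",
    "build_template",
    "synthetic_template",
    "detect_events",
    "qc_voltage_clamp",
    "summarize_events",
    "robust_noise_rms",
]

#: the first-N-events analysis cap
EVENT_CAP = 250
#: QC limits: access resistance (MΩ), baseline change (pA), noise RMS (pA)
RA_LIMIT_MOHM = 30.0
BASELINE_LIMIT_PA = 50.0
NOISE_LIMIT_PA = 8.0


@dataclass(frozen=True)
class Template:
    """Unit-peak detection kernel (dimensionless; positive peak = 1)."""

    waveform: np.ndarray
    dt_ms: float
    rise_ms: float
    decay_ms: float
    provenance: str = "synthetic_kernel"   # or "averaged_events"

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=np.float64)
        object.__setattr__(self, "waveform", w)
        if not np.isclose(np.max(np.abs(w)), 1.0):
            raise ValidationError("waveform: peak magnitude must be 1")
        if not np.all(np.isfinite(w)):
            raise ValidationError("waveform: must be finite")

    @property
    def span_ms(self) -> float:
        """Rise + decay span used as the minimum event separation."""
        return self.rise_ms + self.decay_ms


@dataclass(frozen=True)
class DetectedEvent:
    time_ms: float
    amplitude_pA: float      # positive magnitude of the inward deflection
    criterion: float         # fitted scale / SE of the fit


@dataclass
class VCQC:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    ra_max_mohm: float | None = None
    baseline_change_pA: float | None = None
    noise_rms_pA: float | None = None

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValidationError("passed: must match reasons empty")


@dataclass
class EventSeriesSummary:
    n_analyzed: int
    frequency_hz: float
    mean_amplitude_pA: float | None
    analyzed_duration_s: float


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def synthetic_template(tau_r_ms: float = 0.7, tau_d_ms: float = 5.0,
                       dt_ms: float = 0.05) -> Template:
    """Default difference-of-exponentials kernel (typical CA1 sEPSC shape
    near physiological temperature)."""
    return Template(waveform=epsc_kernel(tau_r_ms, tau_d_ms, dt_ms),
                    dt_ms=dt_ms, rise_ms=tau_r_ms, decay_ms=tau_d_ms,
                    provenance="synthetic_kernel")


def build_template(snippets: Sequence[np.ndarray], dt_ms: float,
                   rise_ms: float = 0.7, decay_ms: float = 5.0,
                   *, min_snippets: int = 10) -> Template:
    """Average aligned event snippets into a unit-peak template.

    Snippets must be equal length with event onsets aligned at sample 0.
    The pointwise mean is baseline-subtracted (first sample) and normalized
    to unit peak magnitude; inward-going averages are flipped so the stored
    kernel peak is positive.
    """
    if len(snippets) < min_snippets:
        raise ValidationError(
            f"snippets: need >= {min_snippets}, got {len(snippets)}")
    lengths = {len(s) for s in snippets}
    if len(lengths) != 1:
        raise ValidationError("snippets: must be equal length")
    mean = np.mean(np.asarray(snippets, dtype=np.float64), axis=0)
    mean = mean - mean[0]
    peak = np.max(np.abs(mean))
    if peak == 0:
        raise ValidationError("snippets: zero peak after averaging")
    w = mean / peak
    if abs(w.min()) > abs(w.max()):
        w = -w
    return Template(waveform=w, dt_ms=dt_ms, rise_ms=rise_ms,
                    decay_ms=decay_ms, provenance="averaged_events")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def criterion_trace(trace: np.ndarray, template: Template
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding scaled-template fit; returns (criterion, fitted scale) per lag.

    At each lag the model ``y = s·T + c`` is solved by least squares over the
    template window, with ``T`` the negated (inward) kernel; the criterion is
    ``s / SE(s)``.  Vectorized with rolling sums.
    """
    T = -template.waveform
    N = T.size
    y = np.asarray(trace, dtype=np.float64)
    if y.size < N:
        return np.empty(0), np.empty(0)
    sum_T = T.sum()
    sum_T2 = float(T @ T)
    den = sum_T2 - sum_T ** 2 / N

    # rolling sums over each length-N window
    c1 = np.cumsum(np.concatenate(([0.0], y)))
    sum_y = c1[N:] - c1[:-N]
    c2 = np.cumsum(np.concatenate(([0.0], y * y)))
    sum_y2 = c2[N:] - c2[:-N]
    sum_Ty = fftconvolve(y, T[::-1], mode="valid")

    s = (sum_Ty - sum_T * sum_y / N) / den
    c = (sum_y - s * sum_T) / N
    sse = sum_y2 - c * sum_y - s * sum_Ty
    sse = np.maximum(sse, 0.0)
    se = np.sqrt(sse / (N - 2) / den)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.where(se > 0, s / se, 0.0)
    return crit, s


def detect_events(trace: Sweep, template: Template,
                  criterion_threshold: float = 4.0) -> list[DetectedEvent]:
    """Detect inward synaptic events on a voltage-clamp sweep.

    Events are criterion local maxima above threshold, at least the
    template's rise+decay span apart; the event time is the lag of the
    best fit (kernel onset) and the amplitude the fitted scale.
    """
    if trace.mode != VOLTAGE_CLAMP:
        raise ValidationError("mode: event detection needs voltage clamp")
    if not np.isclose(trace.dt, template.dt_ms):
        raise ValidationError(
            f"dt: trace dt {trace.dt} ms != template dt {template.dt_ms} ms")
    crit, scale = criterion_trace(trace.samples, template)
    if crit.size == 0:
        return []
    distance = max(int(round(template.span_ms / trace.dt)), 1)
    # the prominence guard keeps noise ripples riding on an event's broad
    # criterion tail from registering as separate events
    peaks, _ = find_peaks(crit, height=criterion_threshold,
                          prominence=criterion_threshold, distance=distance)
    return [DetectedEvent(time_ms=float(p * trace.dt),
                          amplitude_pA=float(scale[p]),
                          criterion=float(crit[p]))
            for p in peaks if scale[p] > 0]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def robust_noise_rms(trace: np.ndarray, dt_ms: float,
                     baseline_window_s: float = 1.0) -> float:
    """Noise RMS as 1.4826 × MAD of the residual after removing a 1 s
    moving-average baseline; sparse synaptic events barely move the MAD."""
    w = max(int(round(baseline_window_s * 1000.0 / dt_ms)), 1)
    resid = trace - uniform_filter1d(trace, size=w, mode="nearest")
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def qc_voltage_clamp(recording: Recording) -> VCQC:
    """Apply the three recording gates (Ra, baseline stability, noise)."""
    sw = recording.sweeps[0]
    if sw.mode != VOLTAGE_CLAMP:
        raise ValidationError("mode: QC needs a voltage-clamp recording")
    reasons: list[str] = []

    ra_max = None
    if recording.access_resistance_series is not None:
        ra_max = float(np.max(recording.access_resistance_series[:, 1]))
        if ra_max > RA_LIMIT_MOHM:
            reasons.append("ra_exceeded")

    n10 = min(int(round(10_000.0 / sw.dt)), sw.n)
    first = float(np.median(sw.samples[:n10]))
    last = float(np.median(sw.samples[-n10:]))
    change = abs(last - first)
    if change >= BASELINE_LIMIT_PA:
        reasons.append("baseline_unstable")

    rms = robust_noise_rms(sw.samples, sw.dt)
    if rms >= NOISE_LIMIT_PA:
        reasons.append("noise_excessive")

    return VCQC(passed=not reasons, reasons=reasons, ra_max_mohm=ra_max,
                baseline_change_pA=change, noise_rms_pA=rms)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize_events(events: Sequence[DetectedEvent],
                     trace_duration_s: float) -> EventSeriesSummary:
    """First-250-events summary.

    With more than 250 events, the analyzed duration is the time of the
    250th event; otherwise the full trace duration.  Frequency = analyzed
    events / analyzed duration.
    """
    times = [e.time_ms for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError("events: must be time-sorted")
    if len(events) > EVENT_CAP:
        kept = list(events[:EVENT_CAP])
        duration_s = kept[-1].time_ms / 1000.0
    else:
        kept = list(events)
        duration_s = trace_duration_s
    n = len(kept)
    freq = n / duration_s if duration_s > 0 else 0.0
    mean_amp = (float(np.mean([e.amplitude_pA for e in kept]))
                if n else None)
    return EventSeriesSummary(n_analyzed=n, frequency_hz=freq,
                              mean_amplitude_pA=mean_amp,
                              analyzed_duration_s=duration_s)
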