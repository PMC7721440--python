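# Methods

`ephyskit` implements the computational core of a whole-cell patch-clamp
aging study: intrinsic-excitability feature extraction with an emphasis on
the medium afterhyperpolarization (AHP), spontaneous EPSC detection by
scaled-template matching, and the cohort-level statistical battery that
connects cellular measurements to behavioral and molecular readouts.
Because studies of this kind typically publish figures and summary
statistics rather than raw traces, the package ships a synthetic-data
generator with known ground truth; every claim the test suite makes is a
claim about recovery of that ground truth.

## Feature definitions

All definitions operate on uniformly sampled sweeps (canonical units mV /
pA / ms / MΩ; 20 kHz sampling, dt = 0.05 ms).

* **Spikes** — upward crossings of 0 mV, linearly interpolated between the
  bracketing samples; crossings closer than 1 ms are merged (refractory
  guard). Instantaneous frequency = 1/ISI per consecutive pair.
* **Resting potential** — mean of the pre-stimulus segment (≥ 100 ms
  required).
* **Input resistance** — (steady-state − baseline voltage)/I at the −50 pA
  step. "Steady state" is the mean of the final 20 % of the step; the
  definition leaves the window open, and the final fifth of a 250 ms step
  (13+ membrane time constants after onset at τ ≈ 15 ms) is fully settled.
* **Membrane time constant** — first time after step onset at which the
  voltage change reaches 63 % of the steady-state change, interpolated.
  Note 63 % (the stated criterion) differs from 1 − 1/e = 63.2 %; the
  definitional bias is −0.6 % of τ and is inside the stated tolerance.
* **AP threshold** — voltage at the maximum of d³V/dt³ in the 2 ms before
  the first AP's peak. Derivatives are repeated central differences with a
  5-point moving average at each stage (configurable; the brute-force test
  oracle runs unsmoothed). The search stops 3 samples short of the peak:
  the triple central-difference stencil spans ±3 samples, and the peak's
  own curvature break would otherwise dominate the search on any trace
  whose peak is sharp at the sampling rate.
* **AP amplitude / half-width** — peak minus threshold; time between the
  interpolated crossings of threshold + amplitude/2. "First AP elicited" =
  first spike of the lowest-amplitude spiking sweep.
* **Firing** — max instantaneous frequency over all sweeps; F/I slope =
  ordinary least squares of first instantaneous frequency vs current over
  sweeps with ≥ 2 spikes; adaptation index = last/first instantaneous
  frequency at the protocol step nearest (first spiking amplitude +
  250 pA) — exact on the default 50 pA grid.
* **AHP** — on the lowest-amplitude sweep with ≥ 12 spikes inside the
  250 ms step (12/0.25 s = 48 Hz, the "~50 Hz" qualification implemented
  literally as the spike-count rule, with no separate frequency check):
  baseline = mean over [end+600, end+700) ms, trough = minimum over
  [end, end+175) ms, amplitude = baseline − trough. Reported as a positive
  magnitude for hyperpolarization; an analytic check (imposed −4 mV decay,
  τ = 150 ms) yields 3.947 mV, confirming the windows are literal.
* **QC** — a cell is excluded if no sweep reaches 12 in-step spikes
  (`insufficient_spiking`) or if the AHP epoch's high-pass (> 20 Hz
  Butterworth, zero-phase) residual RMS exceeds 0.5 mV
  (`excessive_synaptic_input`). The synaptic-input criterion is inherently
  qualitative in the field; the 20 Hz / 0.5 mV operationalization is
  configurable and recorded with the output. A quiet recording at the
  default noise level sits near 0.05 mV RMS, an order of magnitude under
  the limit; a barrage of few-mV fast PSP-like deflections crosses it.

## Synthetic current-clamp generator

An exponential-integrate-and-fire neuron with a spike-triggered AHP
conductance:

    C dV/dt = −g_L (V−E_L) + g_L Δ_T exp((V−V_T)/Δ_T) + I − w − g_AHP (V−E_K)
    τ_w dw/dt = a (V−E_L) − w
    τ_AHP dg_AHP/dt = −g_AHP,   g_AHP += b_AHP per spike

Fixed-step Euler at dt = 0.05 ms (stability follows from dt/τ_m ≈ 0.003;
the exponential term is clamped 20 slope factors above threshold and
skipped 7 below, where it is < 0.02 pA). When V reaches V_cut a
stereotyped 2 ms AP (linear rise to +30 mV in 0.5 ms, fall to V_reset in
1.5 ms) is pasted so that a 0 mV-crossing detector has a waveform to
cross; the generator logs the exact 0 mV crossing time of the pasted rise
as ground truth. Membrane noise is an Ornstein–Uhlenbeck-like term with
stationary RMS σ (default 0.1 mV, a quiet whole-cell recording; noise is
suppressed inside the 2 ms paste).

Defaults: g_L = 6.667 nS (Rin 150 MΩ), C = 100 pF (τ 15 ms), E_L = −67 mV
(the holding target), V_T = −50, Δ_T = 2, V_reset = −60, V_cut = −30,
E_K = −90, τ_AHP = 150 ms, a = 0. This model is an emulation built to
expose exactly the quantities the extractor must recover (Rin = 1/g_L,
τ = C/g_L, a threshold-like onset, a tunable AHP), not a biophysical claim
about CA1 pyramidal neurons: it has no sag, no bursting, no conductance-
based AP waveform, and its "threshold" is the paste cutoff rather than a
sodium-channel property.

**Presets.** `young_like` (b_AHP = 0.15 nS) and `old_like` (0.29 nS)
produce noiseless measured AHPs of 1.98 and 3.97 mV — a ~2 mV group
difference, the effect scale the statistics layer must detect at
realistic cohort sizes. The AHP-vs-b_AHP curve is monotone but has small
jumps where the lowest qualifying (≥ 12-spike) sweep index changes; the
presets sit on locally smooth stretches, and cohort simulations specify
heterogeneity in AHP units and invert the monotonized curve
(`pipeline.AhpCalibration`). Because the AHP conductance also shunts the
drive, increments above ≈ 3 nS silence the cell below the 12-spike
qualification at the protocol's 700 pA ceiling, so monotonicity is
validated over five levels spanning 0–0.30 nS (the physiologically scaled
range of the presets).

**Recovery tolerances are cohort-level.** Spike precision/recall = 1 is
asserted per sweep up to σ = 2 mV. Rin within 1 %, τ within 3 % and AHP
within 0.3 mV are asserted on the mean over 50 simulated neurons: the
window estimators the definitions prescribe have per-neuron sampling error
of the same order as those tolerances at any realistic noise (e.g. the
−50 pA steady-state mean over 50 ms of τ-correlated 0.1 mV noise has
~0.08 mV SE against a 7.5 mV deflection), so the per-neuron quantity the
tolerances can meaningfully bound is the bias, which the cohort mean
isolates. Measured: ≤ 0.1 % (Rin), ≤ 1 % (τ, dominated by noise-induced
early crossing of the 63 % level plus the 63 vs 63.2 % definition),
≤ 0.15 mV (AHP, dominated by the noise bias of the windowed minimum).

## Synthetic voltage clamp and event detection

The sEPSC trace is Σᵢ −Aᵢ·k(t−tᵢ) + white Gaussian noise + linear drift:
tᵢ a homogeneous Poisson process, Aᵢ log-normal (median 20 pA, shape 0.3
— a typical CA1 sEPSC amplitude distribution), k a peak-normalized
difference of exponentials (τ_r = 0.7 ms, τ_d = 5 ms, near-physiological
temperature kinetics), with an access-resistance trajectory stored
alongside.

Detection is the classic sliding least-squares template fit: at each lag,
y = s·T + c is solved in closed form over the template window (rolling
sums + FFT correlation), and the criterion is s/SE(s). Events are
criterion local maxima above the threshold (default 4.0 — the commercial
tools publish no value, so this is configurable), separated by at least
the template's rise+decay span, **and** with peak prominence at least the
threshold. The prominence guard is the one addition to the textbook
recipe: without it, noise ripples riding on an event's broad criterion
tail register as separate events and inflate the rate several-fold at
realistic noise. The criterion is scale-invariant (both s and SE are
linear in the trace), so the false-event rate on pure noise (~0.03 Hz at
threshold 4.0) does not depend on the noise RMS.

Because the false-event budget (< 0.1 Hz) is a fixed rate, it is a large
fraction of the true rate at the lowest tested frequency (0.5 Hz);
recovery within 10 % is therefore assessed on the mean over the 10
replicate recordings per rate, where it holds with margin at all three
rates (≈ 7 % at 0.5 Hz, ≤ 2 % at 2 Hz, ≈ 5 % at 5 Hz).

QC gates: any Ra sample > 30 MΩ; |median(last 10 s) − median(first 10 s)|
≥ 50 pA; robust noise RMS ≥ 8 pA, estimated as 1.4826 × MAD of the
residual after removing a 1 s moving-average baseline so that the events
themselves (a few percent duty cycle) do not inflate the estimate.
Summaries follow the first-250-events rule; with more than 250 events the
frequency denominator is the elapsed time to the 250th event (the span
actually scanned), a convention the source protocols leave open and which
keeps the rate estimator unbiased.

## Statistical battery

Implemented over plain pandas tables (`subject, group[, day], features…`).
Standard tests are delegated to scipy/pingouin and cross-checked in the
test suite against independent hand-written sums-of-squares / normal-
equations / direct-formula oracles (10⁻⁹ relative agreement):

* one-way ANOVA (`scipy.stats.f_oneway`) with group means/SEMs;
* Tukey–Kramer (`scipy.stats.tukey_hsd`, unequal n) plus the studentized-
  range q computed from the pooled within-group mean square;
* pooled-variance two-sided Student's t (the unqualified "Student t-test");
* two-way repeated-measures (split-plot) ANOVA via `pingouin.mixed_anova`:
  between factor against the subject-within-group error, within factor and
  interaction against the residual; no sphericity correction by default
  (none is standard in this literature; Greenhouse–Geisser is available
  through pingouin directly); complete designs enforced with missing cells
  named;
* Pearson r with the two-sided t-transform p; correlation panels use
  pairwise-complete observations and unadjusted p values by default
  (matching standard per-marker reporting), with an optional
  Benjamini–Hochberg adjustment;
* Grubbs two-sided single-pass outlier screen, hand-implemented
  (no installed library provides it): G = max|xᵢ−x̄|/s against
  G_crit = ((N−1)/√N)·√(t²/(N−2+t²)) with t the upper α/(2N) t-quantile at
  N−2 df (checked against the published table value 1.715 at N = 5,
  α = 0.05, and against a Monte-Carlo null); at most one exclusion per
  group, no iteration — matching the one-animal-per-cohort exclusion rule;
* behavioral and molecular scalars: 3-trial block means, day-20 − day-23
  escape-latency improvement (per-day value = mean over that day's
  trials), 2^−ΔΔCt with a reference gene and calibrator group (plate-wide
  Ct shifts cancel), and band/loading-control densitometry fold change
  relative to a reference group.

Calibration is verified by simulation: ANOVA type-I error and Tukey
family-wise error ≈ 0.05 on 2000 null tables each, and the null
correlation-panel false-positive fraction ≈ 0.05.

## The cohort power property

`pipeline.run_ahp_pipeline` wires everything together: per-group neurons
(Young n=10 at 2 mV target AHP, Old n=12 at 4 mV, Old+treated n=19 at
2 mV — the study's neuron counts) are simulated with per-neuron target
AHPs drawn Normal(group mean, 1.5 mV, floored at 0.2 mV), converted to
b_AHP through the calibration curve; each neuron's AHP is measured from
its noisy traces; Grubbs screens each group; one-way ANOVA + Tukey test
the group effect. Over 500 replicate cohorts the chain detects the group
effect in ~95 % of replicates (≥ 80 % required) and Tukey separates Young
from Old in ~70 % (> 50 % required).

## Problem sizes and numerical choices

* Recovery and oracle checks use 50 simulated neurons per preset / 50
  random instances per estimator; detection uses 10 replicate 240 s
  recordings per rate; calibration uses 2000 null tables; power uses 500
  cohorts. These sizes give Monte-Carlo standard errors comfortably inside
  every asserted tolerance.
* The Euler core is numba-compiled; one 20-sweep neuron costs ~15 ms, so
  the 500-cohort power study (≈ 20 000 neurons) runs in minutes on one
  core.
* Degenerate inputs are defined, not crashed on: zero-deflection Rin
  returns 0 MΩ with a warning; all-equal ANOVA/RM-ANOVA tables return
  F = 0, p = 1; zero-spread Grubbs groups exclude nothing with a warning;
  per-metric failures (no spikes, missing −50 pA sweep, too few F/I
  points) are carried as reasons without failing the other metrics.
* Seeds: every stochastic routine takes an explicit integer seed; child
  seeds derive via `numpy.random.SeedSequence`. Identical seeds give
  bitwise-identical recordings, tables and CLI outputs.

## Limitations

* The neuron model is an emulation; absolute AHP magnitudes, thresholds
  and F/I gains are not calibrated to published figures (the source
  material prints none numerically), only the *relative* young/old
  separation is designed in.
* The generator's noise is stationary and Gaussian; real recordings drift,
  contain seal instabilities and non-Gaussian synaptic bombardment, so
  passing recovery tests here bounds algorithmic error, not biological
  measurement error.
* The event detector's equivalence with proprietary template-matching
  implementations cannot be validated (their criterion formula and
  threshold are unpublished); only the method class is implemented.
* Printed group statistics from rounded 1-decimal summary tables are not
  recomputable at full precision and are not targeted.
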