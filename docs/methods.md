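# Methods

This note documents the models implemented in `hfosnn`, the parameter
choices that matter, and where the design was genuinely open. Symbols:
δ (delta-modulator threshold, µV), τ (refractory period, s), fs
(sampling rate, Hz).

## Signal model and preprocessing

The pipeline assumes multichannel ECoG sampled at ≥ 2 kHz in microvolts,
processed independently per (bipolar) channel. Two causal FIR band-pass
filters split each channel: EEG band 4–80 Hz and HFO (fast-ripple) band
250–500 Hz, both 64th-order Hamming-windowed-sinc designs.

Two deliberate choices:

* **Exact DC null.** A 65-tap filter at 2 kHz has a frequency resolution
  of ~30 Hz and cannot realize a 4 Hz transition; the raw windowed-sinc
  design leaves a DC gain of 0.93, so electrode offsets and drift would
  pass straight through. The taps are therefore mean-corrected
  (`sum(taps) = 0`), which places an exact null at DC at the cost of
  strong attenuation below ~10 Hz. This is a physical limitation of any
  64th-order design at this rate, not of the implementation.
* **Bit-identical streaming.** Real-time operation processes the signal
  in blocks (default 32 samples). Each output sample is accumulated
  tap-by-tap in a fixed order from a per-channel delay line, so the
  floating-point operation sequence — and hence the output, bit for
  bit — never depends on how the stream is partitioned. Correctness is
  checked against `scipy.signal.lfilter` to numerical precision.

Filtering is causal; every event timestamp downstream lives in
filtered-signal time, delayed by the constant group delay of
`order/2` samples (16 ms at 2 kHz). The delay is stored in the filter
spec and recording metadata so annotations can be shifted back.

## Delta modulation

The ADM emits an UP (DN) pulse when the signal reaches the threshold
held δ above (below) the current anchor; both thresholds then re-anchor
around the crossed threshold, and a shared refractory period τ imposes
a minimum inter-pulse interval (τ defaults to 0 for both bands; the
protocol defines no value, so it is exposed in config).

**Discretization choice.** In the continuous-time (analog) modulator
the signal value at the crossing instant *is* the threshold, so
"re-anchor at the crossing value" and "re-anchor at the crossed
threshold" coincide. In discrete time they do not: re-anchoring at the
sampled value adds the sampling overshoot to the anchor at every pulse,
and the piecewise-constant decoder — which can only step by ±δ —
accumulates that overshoot as unbounded drift (~6δ on 400-sample test
signals). The implementation re-anchors at the crossed threshold: the
encoder anchor then always equals the decoder's running sum, and the
round-trip error is provably ≤ δ at every sample whenever per-sample
increments stay below δ and τ = 0. A jump of several δ inside one
sample emits a single pulse, with catch-up pulses on subsequent
samples; pulse rate is therefore capped at one per polarity per sample,
and during fast-ripple bursts the reconstruction error transiently
reaches the burst amplitude while the pulse *timing* — which the
spiking core consumes — is preserved.

δ is tuned once per session, per channel and band, on the first 5 s:
the amplitude range (max − min) of non-overlapping windows (50 ms EEG /
5 ms HFO) is collected and δ is the 40th (EEG) / 50th (HFO)
linear-interpolation percentile of that distribution, floored at
`delta_min = 0.1 µV`. Occasional events inside the tuning stretch are
tolerated by construction — a percentile of ~100–1000 window ranges
barely moves when a handful of windows are contaminated.

## Spiking core

Neuron model: current-based leaky integrate-and-fire with an
exponential synapse, integrated with exponential-Euler updates at
`dt = 0.1 ms` (an error is raised if `dt ≥ min(τ)/10`):

    I ← I·exp(−dt/τ_syn) + w·(pulses in dt)
    V ← V·exp(−dt/τ_mem) + (1 − exp(−dt/τ_mem))·g·I

with firing at `V ≥ θ`, reset, and absolute refractory. This is the
simplest model that exposes the bias set the evolutionary tuning
manipulates (τ_mem, τ_syn, θ, w, g, refractory); no claim is made that
it reproduces the analog circuit dynamics of neuromorphic hardware
beyond that interface.

Layout is fixed by the hardware analogy: 10 neurons per population,
ACC UP and ACC DN populations per band per channel (40 neurons per
channel), one 256-neuron core per band, 1024 neurons per chip, at most
8 channels. ACC UP receives only UP pulses, ACC DN only DN pulses
(wiring exclusivity is a tested invariant).

**Mismatch model.** Each neuron's parameters are the core-shared mean
times `1 + N(0, cv_p)`, re-drawn to stay positive and frozen at build
time. `cv_p` is the base cv (default 0.20) scaled per parameter:
1.0 for the bias-current-controlled quantities (time constants,
synaptic weight, refractory), 0.5 for the gain and 0.25 for the firing
threshold, reflecting that sub-threshold bias circuits dominate
fabrication mismatch while the spiking comparator is a much
better-matched structure. A flat 20 % cv on the threshold produces
single neurons ~4× more sensitive than the population median, which
fire tonically on baseline noise; no core-shared operating point then
separates events from baseline, contradicting the working hardware the
layout emulates.

**Shipped operating points.** HFO core: τ_mem 10 ms, τ_syn 4 ms,
w 0.55, θ 1, refractory 30 ms. EEG core: τ_mem 20 ms, τ_syn 10 ms,
w 0.5, θ 1, refractory 100 ms. These were calibrated on synthetic
sessions exactly as the evolutionary procedure would calibrate a real
session: a dense pulse packet (a burst or an IED) drives most of a
population across threshold once, baseline pulse rates stay
sub-threshold, and the refractory period enforces the one-spike-per-
event regime. The per-session `evolve` entry point reproduces such
operating points from a single tuning snippet.

## Evolutionary tuning

Per neuron, `score = −α·|spikes_IN − 1| + β·(spikes_IN − spikes_OUT)`
with α = 2 > β = 1 > 0; the unique maximum β is one IN spike, zero OUT
spikes. The population score — the protocol names the ingredients but
not the combiner — is `mean(neuron scores) − γ·(1 − fraction spiking)`
with γ = 1, so a silent population can never outrank a fully
participating one.

The optimizer is a shrinking-volume elitist random search: sample
configurations uniformly inside the current volumes (log-uniformly for
τ_mem, τ_syn and refractory, which span orders of magnitude; linearly
for θ, w, g), simulate the snippet, score, keep the best `n_elites = 4`
*ever seen* (a persistent pool — recentering on a weaker recent batch
would waste evaluations), recenter the volumes on them and shrink by
0.7. Defaults: 20 samples/iteration, 10 iterations. The best-score
trace is non-decreasing by construction.

The tuning snippet is 8 s of background with one pattern at t = 6 s:
the first 5 s double as the ADM tuning stretch, the IN period covers
the pattern plus a 50 ms tail (shifted by the filter group delay), and
the OUT periods are everything else trimmed 100 ms from the IN edges.
The pattern is a *prominent exemplar* — 3× the typical synthetic event
amplitude — mirroring how an experimenter picks the clearest event of a
session for calibration. With a typical-amplitude exemplar the score's
own optimum tolerates a few OUT spikes (the β-weighted OUT penalty is
cheap against the α-weighted reward for activating marginal neurons);
a clear exemplar removes that tension and the optimum lands on the
sparse code proper.

## Detection

All spikes of a band are convolved with a causal 100 ms boxcar
(`kernel_shape` also accepts triangular) on a 1 ms grid and summed;
maximal positive-activity periods containing both UP and DN spikes are
EoI-HFO candidates. Rules, applied in order with the first failure
recorded:

1. ≥ 2 distinct ACC UP neurons, ≥ 2 distinct ACC DN neurons, ≥ 6
   distinct neurons total ("activations" = distinct neurons, not spike
   counts).
2. UP and DN first-to-last spike intervals overlap (> 0 ms). Untrimmed
   intervals: a stray spike can only widen them, never fake a
   separation.
3. HFO-band spike span ≤ 30 ms.
4. Any overlapping EEG-band activity has spike span ≤ 500 ms.

IED-HFO upgrade: co-occurring EEG activity whose UP and DN intervals
are disjoint with ≥ 10 ms gap and whose span is ≤ 300 ms.

Durations are measured on raw spike spans, not the kernel-widened
trace, so the 100 ms kernel cannot inflate a 30 ms criterion — and
spans (rules 3, 4, IED) use the central-90 % spike interval
(5th–95th nearest-spike quantiles, applied from 5 spikes up,
`span_trim` in config): with 20 % device mismatch the single most
sensitive neuron of a population occasionally fires on baseline, and
one such stray spike landing within kernel reach of a genuine 15 ms
burst would otherwise stretch the measured span past 30 ms.

Rates are accepted events per channel per kind divided by the recording
duration in minutes; the clinical decision threshold is ≥ 1/min
(inclusive).

## Clinical statistics

TP/FP/FN/TN per patient from the post-resection rate vs the ILAE
outcome class (1 = seizure-free); PPV, NPV, sensitivity, specificity,
accuracy as the standard ratios, with zero-denominator metrics flagged
as undefined rather than reported as 0. Clopper–Pearson exact binomial
CIs via beta quantiles (endpoints exactly 0/1 at the boundaries);
Spearman correlation two-sided with average ranks for ties, undefined
(flagged NaN) for constant input. The shipped 22-patient cohort table
(`hfosnn/data/usz_cohort.csv`) stores sub-threshold rates reported only
as "<1" as 0.5 — any value below the threshold is equivalent for
classification. The IED-HFO analysis applies a per-patient override
(one patient whose post-resection recording contained no IED at all is
forced FN), mirroring how rate-based classification cannot express
that judgement call.

## Reconstruction

Rate-network dynamics `τ ẋ = −x + J·tanh(x) + W_in·s(t) [+ W_hint·y]`
with N = 300 units, τ = 10 ms, dt = 1 ms. Spike trains enter through a
20 ms exponential kernel, one input channel per spiking neuron (20 per
band-channel). Teacher: fixed random `J` with spectral scale g plus the
target as a hint input; student: same `J` initially, recurrent weights
adapted by RLS (update every 2 steps, initial inverse-correlation scale
λ = 1, 3 passes) to match the teacher's internal drive; readout: ridge
regression from student rates to the normalized target.

Two hyperparameters departed from common full-FORCE practice after
measurement: `g = 0.9` (instead of the chaotic 1.5) with
`input_scale = 4` and `hint_scale = 0.3`, because with a sparse
20-channel spike drive the chaotic regime's spontaneous dynamics drown
the input and the readout memorizes training states (median test r
~0.05 vs ~0.8 in the input-driven regime); and a readout ridge of 1e-4
relative to the mean diagonal of the state covariance — light,
conventional shrinkage that leaves the normal train ≥ test gap while
preventing outright memorization.

Snippets: segments where both populations fired and the spike span is
≤ 500 ms, padded by 100 ms, split chronologically (first quarter =
train). Evaluation is per-snippet Pearson r between target and
reconstruction, with the median per split; constant-target snippets
are flagged and excluded. The inference interface takes only spikes —
the target cannot leak at reconstruction time.

## Synthetic data: what it does and does not emulate

Background is spectrally shaped Gaussian noise (power ∝ 1/f², flat
below 1 Hz, exponent configurable), normalized to 50 µV RMS per
channel; channels are independent. Events: Hann-windowed fast-ripple
bursts (250–500 Hz, 15–30 ms, 20 µV peak — well above the ~2 µV
noise floor of the 250–500 Hz band but far below the broadband
background); difference-of-Gaussians IEDs (sharp negative spike, then a
broad positive wave; 100–180 ms, 300 µV); IED-HFO composites with the
burst centered on the fast spike; 500 µV boxcar step artifacts (50 ms
hold, one-sample edges) whose edge rings are the classic source of
false HFOs; and ≥ 1 s, 800 µV low-frequency (12 Hz) artifacts with fast
edges — 12 Hz rather than lower so the artifact body actually passes
the DC-nulled EEG filter and exercises the long-coactivity rejection.
Placement is uniform rejection sampling with a 250 ms minimum gap and
bounded retries; everything is deterministic given (config, seed).

What passing tests on this data shows: the chain separates
band-limited oscillatory packets from filter ringing and from
high-amplitude excursions at realistic SNR, with exact ground truth.
What it does not show: performance on real ECoG — synthetic events are
more stereotyped than biological HFOs, background is stationary and
Gaussian (no spindles, no state changes, no anesthesia effects), and
channels carry no spatial correlation. The clinical module's cohort
table is an input dataset, not something the detector is validated on
end-to-end here.

## Validation problem sizes

The end-to-end suite uses a 10-minute, 2-channel session with 20 HFO,
10 IED-HFO, 10 step and 5 long artifacts (≥ 80 % recovery, zero
artifact accepts, compression chain `T > N_UP+N_DN > ΣNᵢ`); the
optimizer check runs 5 iterations × 20 samples on one snippet; the
reconstruction check trains on a 2-minute single-channel session dense
in IEDs (~40 events, first quarter train). Codec properties are checked
against a literal step-through oracle on 100 random bounded-increment
signals. These sizes keep the full suite in the low minutes on one CPU
while leaving each check's margin wide (observed: recovery ≥ 93 %
across seeds, optimizer OUT ≤ 0.2, reconstruction median test r
0.76–0.87).

## Known limitations

* The LIF stand-in and the mismatch sensitivities are declared
  approximations of analog hardware; none of the analog circuit
  behavior (bias coupling, temperature drift, AER link limits) is
  modeled.
* Pulse rate is capped at one per polarity per sample; at 2 kHz this
  truncates pulse counts inside the strongest fast-ripple cycles
  (both encoder conventions share this ceiling).
* The "temporally mixed" / "well separated" operationalizations
  (interval overlap > 0; gap ≥ 10 ms) are numeric choices the protocol
  leaves qualitative; both are configurable.
* The evolutionary optimizer is a random search; it finds good
  operating points for a 6-parameter space in ~100 evaluations but has
  no convergence guarantee.
* Reconstruction trains per-snippet from a zeroed network state; a
  continuous-stream decoder would need to handle inter-event drift.
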