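# hfosnn

Spiking-network detection of epileptiform patterns in intraoperative
electrocorticography (ECoG), in software.

High-frequency oscillations (HFO, here the fast-ripple band 250–500 Hz)
and interictal epileptiform discharges (IED) mark epileptogenic cortex:
if the ECoG recorded *after* a resection still contains them at a rate
of ≥ 1/min, the patient is unlikely to become seizure-free. Turning that
into an intraoperative tool requires detecting rare, brief (tens of ms),
low-amplitude events in real time while rejecting the sharp transients
and high-amplitude excursions that plague operating-room recordings.

This package re-creates a neuromorphic real-time detection chain as an
ordinary Python library:

1. **Preprocessing** — bipolar re-referencing and causal streaming FIR
   band-pass filtering (64th order) into an EEG band (4–80 Hz) and an
   HFO band (250–500 Hz). Block-wise output is bit-identical to offline
   filtering.
2. **Delta modulation (ADM)** — each band is compressed to UP/DN pulses:
   a pulse fires whenever the signal moves by δ, where δ is tuned per
   channel as a percentile of the amplitude-range distribution of a 5 s
   baseline (40 % of 50 ms windows for EEG, 50 % of 5 ms windows for
   HFO). The decoder `x̂(t⁺) = x̂(t⁻) ± δ` bounds the round-trip error
   by δ under slow variation.
3. **Spiking core** — per channel, four populations of 10 leaky
   integrate-and-fire neurons (ACC UP / ACC DN per band) mirror a
   1024-neuron, 4-core neuromorphic chip layout (40 neurons/channel,
   up to 8 channels). Device mismatch is emulated as frozen per-neuron
   parameter jitter (cv up to 20 %); the resulting heterogeneity
   decorrelates the population response, which the detection rules
   exploit.
4. **Detection** — spikes are smoothed with a 100 ms kernel; a
   candidate period must show ≥ 2 UP and ≥ 2 DN neurons and ≥ 6 total,
   temporally mixed UP/DN activity, HFO-band span ≤ 30 ms, and no
   overlapping EEG-band activity longer than 500 ms. An accepted HFO
   with co-occurring well-separated EEG activity ≤ 300 ms is an
   IED-HFO.
5. **Evolutionary tuning** — core-shared neuron biases are optimized on
   a single pulse-encoded tuning snippet with the score
   `−α·|spikes_IN − 1| + β·(spikes_IN − spikes_OUT)` (α > β > 0), whose
   optimum is a sparse temporal code: one spike per neuron, just after
   the pattern.
6. **Clinical statistics** — per-patient TP/FP/FN/TN from post-resection
   rates vs ILAE outcome, PPV/NPV/sensitivity/specificity/accuracy,
   exact Clopper–Pearson 95 % CIs, two-sided Spearman correlation.
7. **Reconstruction** — a full-FORCE-trained recurrent network (teacher
   with target hint, student trained by recursive least squares, linear
   readout) rebuilds the continuous trace from the sparse spikes,
   validating that the compression keeps signal morphology.

A first-class synthetic-ECoG generator (pink-noise background with
injected HFO, IED, IED-HFO, step and long artifacts, plus an exact
injection log) makes the whole chain testable without patient data.

## Worked example

`examples/` contains one narrative script per capability. The detection
chain end to end (`python examples/03_detect_events.py`) builds a two
channel, 2-minute synthetic session with 6 HFO, 3 IED-HFO, 3 step
artifacts and 1 long artifact, runs all four stages and scores the
result against the injection log:

```
accepted events (kind, channel, start s):
  HFO      ch0    3.157
  IED_HFO  ch0   58.842
  HFO      ch0   94.667
  IED_HFO  ch0  112.001
  HFO      ch1    0.663
  ...
candidates rejected by the rules: 3
    60.699  rule3_too_long
    ...
per-channel rates (events/min):
 channel    kind  count  rate_per_min
       0     HFO      2           1.0
       0 IED_HFO      2           1.0
       1     HFO      5           2.5
       1 IED_HFO      0           0.0

ground-truth recovery: {
 "hfo_detected": 6, "ied_hfo_detected": 3, "sensitivity": 1.0,
 "artifact_accepted": 0, "false_detections": 0, ...
}
compression chain: T=960000 > pulses=5654 > spikes=493
```

All 9 injected epileptiform events are recovered, no artifact survives
the rules, and the two compression stages shrink 960 000 samples to
5 654 pulses and then 493 spikes — the `T > N_UP + N_DN > Σ Nᵢ` chain
that makes remote real-time analysis feasible.

The same pipeline is available as a thin CLI
(`hfosnn simulate-data | tune | encode | decode | train-snn | detect |
stats | reconstruct | run`, each taking `--config/--seed/--out-dir`),
driven by one YAML file; `hfosnn show-config` prints the defaults, in
which every protocol constant lives.

## Layout

```
src/hfosnn/        library (synthetic, preprocessing, adm, snn,
                   evolution, detection, clinical, reconstruction,
                   pipeline, config, cli)
examples/          one narrative script per capability
tests/             pytest suite (unit, property and end-to-end tests)
docs/methods.md    models, parameters, design choices, limitations
scripts/           acceptance script
```
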