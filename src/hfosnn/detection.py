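"""Rule-based event detection on accumulator-network spike rasters.

Spikes from every neuron of a band are convolved with a 100 ms kernel
and summed into one activity trace per band per channel (ACC UP / ACC
DN component traces are kept as well). Maximal intervals of positive
HFO-band activity containing both UP and DN spikes are candidate events
of interest (EoI-HFO). A candidate is accepted as an HFO only if it
passes, in order,

1. ≥ 2 distinct ACC UP neurons, ≥ 2 distinct ACC DN neurons, and ≥ 6
   distinct neurons in total (rejects low-voltage fluctuations);
2. UP and DN activity temporally mixed — the UP and DN first-to-last
   spike intervals overlap (sharp transients ring through the band-pass
   filter and drive UP and DN at separated times);
3. raw HFO-band spike span ≤ 30 ms;
4. any overlapping EEG-band activity has spike span ≤ 500 ms (rejects
   long high-amplitude artifacts that bleed into the HFO band).

An accepted HFO is upgraded to IED-HFO when EEG-band activity co-occurs
whose UP and DN spike intervals are *well separated* (disjoint with a
minimum gap) and whose span is ≤ 300 ms — the signature of the sharp
spike / slow wave of an interictal discharge.

Durations in rules 3/4 and the IED criterion are measured on raw spike
spans, not on the kernel-widened trace, so the 100 ms kernel does not
inflate a 30 ms criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .snn import BANDS, SpikeRaster

__all__ = [
    "DetectionRules",
    "ActivityTrace",
    "DetectedEvent",
    "smooth_activity",
    "segment_eoi",
    "classify_hfo",
    "classify_ied_hfo",
    "detect_channel",
    "detect",
    "event_rates",
    "write_events",
]


@dataclass(frozen=True)
class DetectionRules:
    """Thresholds of the acceptance/rejection rules (times in seconds)."""

    kernel_duration: float = 0.100
    kernel_shape: str = "boxcar"  # or "triangular"
    min_up_activations: int = 2
    min_dn_activations: int = 2
    min_total_neurons: int = 6
    max_hfo_duration: float = 0.030
    max_eeg_coactivity: float = 0.500
    max_ied_duration: float = 0.300
    mixing_min_overlap: float = 0.0  # UP/DN interval overlap must exceed this
    separation_min_gap: float = 0.010  # gap required for "well separated"
    span_trim: float = 0.05  # quantile trim for robust spike spans
    grid_dt: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "kernel_duration", "max_hfo_duration", "max_eeg_coactivity",
            "max_ied_duration", "grid_dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kernel_shape not in ("boxcar", "triangular"):
            raise ValueError("kernel_shape must be 'boxcar' or 'triangular'")


@dataclass
class ActivityTrace:
    """Smoothed summed spiking activity on a regular grid, per population."""

    grid_dt: float
    total: np.ndarray
    up: np.ndarray
    dn: np.ndarray

    def times(self) -> np.ndarray:
        return np.arange(len(self.total)) * self.grid_dt


@dataclass
class DetectedEvent:
    kind: str  # EoI_HFO | HFO | IED_HFO
    channel: int
    start: float
    end: float
    neuron_ids: list[tuple[str, int]] = field(default_factory=list)
    rejection_reason: str | None = None
    trace_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("event must have start < end")


def _kernel(rules: DetectionRules) -> np.ndarray:
    n = max(int(round(rules.kernel_duration / rules.grid_dt)), 1)
    if rules.kernel_shape == "boxcar":
        return np.ones(n)
    return np.linspace(1, 0, n, endpoint=False)  # causal triangular decay


def smooth_activity(
    raster: SpikeRaster, channel: int, band: str, rules: DetectionRules,
    duration: float | None = None,
) -> ActivityTrace:
    """Causal kernel smoothing: each spike contributes over [t, t+kernel)."""
    duration = raster.duration if duration is None else duration
    n = int(np.ceil(duration / rules.grid_dt)) + 1
    kern = _kernel(rules)
    out = {}
    for pop in ("ACC_UP", "ACC_DN"):
        sub = raster.select(channel=channel, band=band, pop=pop)
        counts = np.zeros(n)
        if len(sub):
            idx = np.minimum(np.floor(sub.times / rules.grid_dt).astype(np.int64), n - 1)
            np.add.at(counts, idx, 1.0)
        out[pop] = np.convolve(counts, kern)[:n]
    return ActivityTrace(
        grid_dt=rules.grid_dt, total=out["ACC_UP"] + out["ACC_DN"],
        up=out["ACC_UP"], dn=out["ACC_DN"],
    )


def segment_eoi(trace: ActivityTrace) -> list[dict]:
    """Maximal intervals with positive activity, annotated with UP/DN presence."""
    active = trace.total > 0
    padded = np.concatenate([[False], active, [False]])
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    segments = []
    for a, b in zip(run_starts, run_ends):
        t0, t1 = a * trace.grid_dt, b * trace.grid_dt
        has_up = bool(np.any(trace.up[a:b] > 0))
        has_dn = bool(np.any(trace.dn[a:b] > 0))
        segments.append(
            {"start": t0, "end": t1, "has_up": has_up, "has_dn": has_dn,
             "is_eoi": has_up and has_dn}
        )
    return segments


def _spikes_in(raster: SpikeRaster, channel: int, band: str, t0: float, t1: float):
    sub = raster.select(channel=channel, band=band)
    m = (sub.times >= t0) & (sub.times < t1)
    return sub.times[m], sub.pop_idx[m], sub.unit_idx[m]


def _interval(times: np.ndarray, trim: float = 0.0) -> tuple[float, float]:
    """First-to-last spike interval; with ``trim`` > 0, the central
    [trim, 1 − trim] quantile span (nearest-spike quantiles), which makes
    duration rules robust to an isolated stray spike from the single
    most mismatch-sensitive neuron of a population."""
    if trim > 0 and len(times) >= 5:
        lo = np.quantile(times, trim, method="higher")
        hi = np.quantile(times, 1.0 - trim, method="lower")
        return float(lo), float(hi)
    return float(times.min()), float(times.max())


def classify_hfo(
    candidate: dict, raster: SpikeRaster, channel: int, rules: DetectionRules,
    eeg_segments: list[dict] | None = None,
) -> DetectedEvent:
    """Apply rules 1–4 in order; the first failure is the rejection reason."""
    t0, t1 = candidate["start"], candidate["end"]
    times, pops, units = _spikes_in(raster, channel, "HFO", t0, t1)
    up_units = set(units[pops == 0].tolist())
    dn_units = set(units[pops == 1].tolist())
    neuron_ids = [("ACC_UP", u) for u in sorted(up_units)] + [
        ("ACC_DN", u) for u in sorted(dn_units)
    ]
    if len(times):
        span_start, span_end = _interval(times, rules.span_trim)
    else:
        span_start, span_end = t0, t1

    def rejected(reason: str) -> DetectedEvent:
        return DetectedEvent(
            kind="EoI_HFO", channel=channel, start=span_start,
            end=max(span_end, span_start + rules.grid_dt), neuron_ids=neuron_ids,
            rejection_reason=reason, trace_interval=(t0, t1),
        )

    # rule 1: population participation
    if (
        len(up_units) < rules.min_up_activations
        or len(dn_units) < rules.min_dn_activations
        or len(up_units) + len(dn_units) < rules.min_total_neurons
    ):
        return rejected("rule1_insufficient_neurons")

    # rule 2: temporal mixing of UP and DN activity; untrimmed intervals —
    # a stray spike can only widen them, never fake a separation
    u0, u1 = _interval(times[pops == 0])
    d0, d1 = _interval(times[pops == 1])
    overlap = min(u1, d1) - max(u0, d0)
    if overlap <= rules.mixing_min_overlap:
        return rejected("rule2_up_dn_separated")

    # rule 3: HFO-band spike span
    if span_end - span_start > rules.max_hfo_duration:
        return rejected("rule3_too_long")

    # rule 4: overlapping EEG-band activity must be short
    if eeg_segments:
        for seg in eeg_segments:
            if max(seg["start"], t0) < min(seg["end"], t1):
                e_times, _, _ = _spikes_in(
                    raster, channel, "EEG", seg["start"], seg["end"]
                )
                if len(e_times):
                    e0, e1 = _interval(e_times, rules.span_trim)
                    if e1 - e0 > rules.max_eeg_coactivity:
                        return rejected("rule4_long_eeg_coactivity")

    return DetectedEvent(
        kind="HFO", channel=channel, start=span_start,
        end=max(span_end, span_start + rules.grid_dt), neuron_ids=neuron_ids,
        trace_interval=(t0, t1),
    )


def classify_ied_hfo(
    hfo_event: DetectedEvent, raster: SpikeRaster, rules: DetectionRules,
    eeg_segments: list[dict],
) -> DetectedEvent:
    """Upgrade an accepted HFO to IED-HFO when a co-occurring IED signature exists."""
    if hfo_event.kind != "HFO":
        raise ValueError("classify_ied_hfo expects an accepted HFO event")
    assert hfo_event.trace_interval is not None
    t0, t1 = hfo_event.trace_interval
    ch = hfo_event.channel
    for seg in eeg_segments:
        if not (max(seg["start"], t0) < min(seg["end"], t1)):
            continue
        times, pops, _ = _spikes_in(raster, ch, "EEG", seg["start"], seg["end"])
        if not (np.any(pops == 0) and np.any(pops == 1)):
            continue
        s0, s1 = _interval(times, rules.span_trim)
        if s1 - s0 > rules.max_ied_duration:
            continue
        u0, u1 = _interval(times[pops == 0], rules.span_trim)
        d0, d1 = _interval(times[pops == 1], rules.span_trim)
        gap = max(u0, d0) - min(u1, d1)  # positive iff intervals disjoint
        if gap >= rules.separation_min_gap:
            return DetectedEvent(
                kind="IED_HFO", channel=ch, start=min(hfo_event.start, float(times.min())),
                end=max(hfo_event.end, float(times.max())), neuron_ids=hfo_event.neuron_ids,
                trace_interval=hfo_event.trace_interval,
            )
    return hfo_event


def detect_channel(
    raster: SpikeRaster, channel: int, rules: DetectionRules = DetectionRules(),
    duration: float | None = None,
) -> list[DetectedEvent]:
    """Full per-channel detection: smoothing, segmentation, rules, IED logic."""
    hfo_trace = smooth_activity(raster, channel, "HFO", rules, duration)
    eeg_trace = smooth_activity(raster, channel, "EEG", rules, duration)
    eeg_segments = segment_eoi(eeg_trace)
    events: list[DetectedEvent] = []
    for candidate in segment_eoi(hfo_trace):
        if not candidate["is_eoi"]:
            continue
        ev = classify_hfo(candidate, raster, channel, rules, eeg_segments)
        if ev.kind == "HFO":
            ev = classify_ied_hfo(ev, raster, rules, eeg_segments)
        events.append(ev)
    return events


def detect(
    raster: SpikeRaster, rules: DetectionRules = DetectionRules(),
    duration: float | None = None,
) -> list[DetectedEvent]:
    events: list[DetectedEvent] = []
    for ch in range(len(raster.channels)):
        events.extend(detect_channel(raster, ch, rules, duration))
    return events


def accepted(events: list[DetectedEvent]) -> list[DetectedEvent]:
    return [e for e in events if e.kind in ("HFO", "IED_HFO")]


def event_rates(
    events: list[DetectedEvent], recording_duration: float, n_channels: int | None = None,
) -> pd.DataFrame:
    """Accepted-event rates in events/min, per channel and kind."""
    if recording_duration <= 0:
        raise ValueError("recording duration must be positive")
    minutes = recording_duration / 60.0
    channels = sorted({e.channel for e in events})
    if n_channels is not None:
        channels = list(range(n_channels))
    rows = []
    for ch in channels:
        for kind in ("HFO", "IED_HFO"):
            n = sum(1 for e in events if e.channel == ch and e.kind == kind)
            rows.append({"channel": ch, "kind": kind, "count": n, "rate_per_min": n / minutes})
    return pd.DataFrame(rows)


def write_events(
    events: list[DetectedEvent], path: str | Path, channels: list[str] | None = None,
) -> None:
    """BIDS-events-style TSV: onset, duration, channel, kind, rejection_reason."""
    rows = [
        {
            "onset": e.start,
            "duration": e.end - e.start,
            "channel": channels[e.channel] if channels else e.channel,
            "kind": e.kind,
            "rejection_reason": e.rejection_reason or "n/a",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["onset", "duration", "channel", "kind", "rejection_reason"]).to_csv(
        path, sep="\t", index=False
    )
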