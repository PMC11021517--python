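"""Ground-truthed synthetic ECoG for exercising the detection pipeline.

Real intraoperative ECoG is not required anywhere in this package: this
module fabricates multichannel recordings made of spectrally shaped (pink)
background noise with injected events of five kinds,

* ``hfo`` — a Hann-windowed fast-ripple burst (250–500 Hz, a few tens of
  milliseconds, low amplitude),
* ``ied`` — an interictal epileptiform discharge: a sharp biphasic
  transient (fast spike followed by a slower wave of opposite polarity),
* ``ied_hfo`` — an IED with an HFO burst riding on its fast component,
* ``step_artifact`` — a sharp boxcar baseline jump whose edges ring
  through a band-pass filter,
* ``long_artifact`` — a long (≥ 1 s) high-amplitude low-frequency
  excursion with fast edges.

Every injection is logged in a :class:`GroundTruth` table so detection
performance can be scored exactly. Channels are generated independently
(the pipeline also processes them independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EcogRecording, write_native

__all__ = [
    "SyntheticConfig",
    "GroundTruthEvent",
    "GroundTruth",
    "InvalidConfigError",
    "PlacementError",
    "EVENT_KINDS",
    "generate_background",
    "synthesize_event_waveform",
    "generate_recording",
]

EVENT_KINDS = ("ied", "hfo", "ied_hfo", "step_artifact", "long_artifact")


class InvalidConfigError(ValueError):
    """Raised when a SyntheticConfig violates its invariants."""


class PlacementError(RuntimeError):
    """Raised when events cannot be placed without violating spacing."""


def _default_counts() -> dict[str, int]:
    return {k: 0 for k in EVENT_KINDS}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic recording.

    Amplitudes are in microvolts; the defaults emulate interictal ECoG:
    ~50 µV RMS broadband background with a power spectrum falling as
    1/f^2, IEDs an order of magnitude above background, HFOs well below
    it broadband but well above the noise floor of the 250–500 Hz band,
    and artifacts larger than everything else.
    """

    n_channels: int = 2
    duration: float = 60.0
    fs: float = 2000.0
    seed: int = 0
    background_amplitude: float = 50.0
    event_counts: dict[str, int] = field(default_factory=_default_counts)
    hfo_freq_range: tuple[float, float] = (250.0, 500.0)
    hfo_duration_range: tuple[float, float] = (0.015, 0.030)  # s
    ied_duration_range: tuple[float, float] = (0.100, 0.180)  # s
    hfo_amplitude: float = 20.0
    ied_amplitude: float = 300.0
    step_amplitude: float = 500.0
    step_hold: float = 0.050  # s between the two edges of the boxcar
    long_artifact_amplitude: float = 800.0
    long_artifact_duration_range: tuple[float, float] = (1.0, 1.6)  # s
    min_event_gap: float = 0.250  # s
    background_exponent: float = 2.0  # power ~ 1/f**exponent
    edge_pad: float = 0.5  # s kept event-free at both ends

    def validate(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise InvalidConfigError("duration and fs must be positive")
        if self.n_channels < 1:
            raise InvalidConfigError("need at least one channel")
        if self.fs < 2 * self.hfo_freq_range[1]:
            raise InvalidConfigError(
                f"fs={self.fs} cannot represent HFOs up to {self.hfo_freq_range[1]} Hz"
            )
        for name in ("hfo_duration_range", "ied_duration_range", "long_artifact_duration_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InvalidConfigError(f"{name} must be positive and ordered")
        unknown = set(self.event_counts) - set(EVENT_KINDS)
        if unknown:
            raise InvalidConfigError(f"unknown event kinds: {sorted(unknown)}")
        if any(v < 0 for v in self.event_counts.values()):
            raise InvalidConfigError("event counts must be >= 0")

    def with_counts(self, **counts: int) -> "SyntheticConfig":
        merged = _default_counts()
        merged.update(self.event_counts)
        merged.update(counts)
        return replace(self, event_counts=merged)


@dataclass(frozen=True)
class GroundTruthEvent:
    kind: str
    channel: int
    onset: float
    offset: float


@dataclass
class GroundTruth:
    """Injection log: one entry per injected event, non-overlapping per channel."""

    events: list[GroundTruthEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_kind(self, kind: str) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.kind, e.channel, e.onset, e.offset) for e in self.events],
            columns=["kind", "channel", "onset_s", "offset_s"],
        )

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "GroundTruth":
        df = pd.read_csv(path, sep=sep)
        return cls(
            [
                GroundTruthEvent(r.kind, int(r.channel), float(r.onset_s), float(r.offset_s))
                for r in df.itertuples()
            ]
        )


def _pink_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shape, n=n)
    return out


def generate_background(config: SyntheticConfig) -> EcogRecording:
    """Pink-noise background, each channel normalized to the configured RMS."""
    config.validate()
    n = int(round(config.duration * config.fs))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_channels)
    data = np.empty((config.n_channels, n))
    for ch, ss in enumerate(seeds):
        x = _pink_noise(n, config.fs, config.background_exponent, np.random.default_rng(ss))
        rms = np.sqrt(np.mean(x**2))
        data[ch] = x * (config.background_amplitude / rms)
    labels = [f"CH{c + 1:02d}" for c in range(config.n_channels)]
    return EcogRecording(data=data, fs=config.fs, channels=labels, meta={"synthetic": True})


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _smooth_edge(n: int) -> np.ndarray:
    """Raised-cosine ramp 0 -> 1 over n samples."""
    return 0.5 * (1 - np.cos(np.pi * np.arange(1, n + 1) / n))


def synthesize_event_waveform(kind: str, fs: float, **params) -> np.ndarray:
    """Return the additive waveform (µV) for one event of the given kind.

    Parameters depend on ``kind``:

    * ``hfo``: ``freq`` (Hz), ``duration`` (s), ``amplitude`` (µV peak).
      A Hann-windowed sinusoid; the duration is extended if needed so the
      burst always contains at least 4 full cycles.
    * ``ied``: ``duration`` (s), ``amplitude`` (µV peak). Difference of
      Gaussians: sharp negative spike followed by a broad positive wave.
    * ``step_artifact``: ``amplitude``, ``hold`` (s). A boxcar with
      one-sample edges; band-pass filtering rings at both edges.
    * ``long_artifact``: ``amplitude``, ``duration`` (s, ≥ 1 s enforced).
      A high-amplitude low-frequency (12 Hz) oscillation with fast
      raised-cosine onset/offset edges: sustained energy in the EEG
      band for the whole excursion, plus edge ringing in the HFO band.
    """
    if kind == "hfo":
        freq = float(params["freq"])
        duration = max(float(params["duration"]), 4.0 / freq)
        amplitude = float(params["amplitude"])
        n = max(int(round(duration * fs)), 2)
        t = np.arange(n) / fs
        return amplitude * np.hanning(n) * np.sin(2 * np.pi * freq * t)

    if kind == "ied":
        duration = float(params["duration"])
        amplitude = float(params["amplitude"])
        n = max(int(round(duration * fs)), 2)
        t = np.arange(n) / fs
        spike_c = 0.18 * duration
        spike_sigma = 0.045 * duration
        wave_c = 0.55 * duration
        wave_sigma = 0.20 * duration
        w = -_gauss(t, spike_c, spike_sigma) + 0.45 * _gauss(t, wave_c, wave_sigma)
        peak = np.max(np.abs(w))
        return amplitude * w / peak

    if kind == "step_artifact":
        amplitude = float(params["amplitude"])
        hold = float(params.get("hold", 0.050))
        n = max(int(round(hold * fs)), 2)
        return np.full(n, amplitude)

    if kind == "long_artifact":
        amplitude = float(params["amplitude"])
        duration = max(float(params["duration"]), 1.0)
        n = int(round(duration * fs))
        t = np.arange(n) / fs
        env = np.ones(n)
        edge = max(int(round(0.005 * fs)), 1)
        env[:edge] = _smooth_edge(edge)
        env[-edge:] = _smooth_edge(edge)[::-1]
        return amplitude * env * np.sin(2 * np.pi * 12.0 * t + 0.5 * np.pi)

    raise ValueError(f"unknown event kind {kind!r}")


def _ied_spike_center_fraction() -> float:
    # the HFO of an ied_hfo composite is centered on the IED fast spike
    return 0.18


def _draw_event(kind: str, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if kind == "hfo":
        return synthesize_event_waveform(
            "hfo",
            config.fs,
            freq=rng.uniform(*config.hfo_freq_range),
            duration=rng.uniform(*config.hfo_duration_range),
            amplitude=config.hfo_amplitude,
        )
    if kind == "ied":
        return synthesize_event_waveform(
            "ied",
            config.fs,
            duration=rng.uniform(*config.ied_duration_range),
            amplitude=config.ied_amplitude,
        )
    if kind == "ied_hfo":
        ied = synthesize_event_waveform(
            "ied",
            config.fs,
            duration=rng.uniform(*config.ied_duration_range),
            amplitude=config.ied_amplitude,
        )
        hfo = synthesize_event_waveform(
            "hfo",
            config.fs,
            freq=rng.uniform(*config.hfo_freq_range),
            duration=rng.uniform(*config.hfo_duration_range),
            amplitude=config.hfo_amplitude,
        )
        w = ied.copy()
        center = int(round(_ied_spike_center_fraction() * len(ied)))
        start = max(center - len(hfo) // 2, 0)
        stop = min(start + len(hfo), len(w))
        w[start:stop] += hfo[: stop - start]
        return w
    if kind == "step_artifact":
        return synthesize_event_waveform(
            "step_artifact", config.fs, amplitude=config.step_amplitude, hold=config.step_hold
        )
    if kind == "long_artifact":
        return synthesize_event_waveform(
            "long_artifact",
            config.fs,
            amplitude=config.long_artifact_amplitude,
            duration=rng.uniform(*config.long_artifact_duration_range),
        )
    raise ValueError(f"unknown event kind {kind!r}")


def generate_recording(config: SyntheticConfig) -> tuple[EcogRecording, GroundTruth]:
    """Background plus randomly placed non-overlapping events.

    Placement is rejection sampling: positions are drawn uniformly within
    the padded recording and accepted only if the new interval keeps
    ``min_event_gap`` seconds clear of every event already on the same
    channel. Raises :class:`PlacementError` after 2000 failed draws for
    any single event (the recording is then too crowded for the request).
    """
    config.validate()
    rec = generate_background(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(config.n_channels + 1)[-1])
    occupied: dict[int, list[tuple[float, float]]] = {c: [] for c in range(config.n_channels)}
    truth = GroundTruth()

    todo: list[str] = []
    for kind in EVENT_KINDS:  # fixed order for determinism
        todo.extend([kind] * int(config.event_counts.get(kind, 0)))

    for kind in todo:
        w = _draw_event(kind, config, rng)
        length = len(w) / config.fs
        lo = config.edge_pad
        hi = config.duration - config.edge_pad - length
        if hi <= lo:
            raise PlacementError(f"{kind} of {length:.3f}s does not fit in the recording")
        for _ in range(2000):
            ch = int(rng.integers(config.n_channels))
            onset = rng.uniform(lo, hi)
            offset = onset + length
            ok = all(
                offset + config.min_event_gap <= a or b + config.min_event_gap <= onset
                for a, b in occupied[ch]
            )
            if ok:
                break
        else:
            raise PlacementError(f"could not place {kind} without overlap")
        i0 = int(round(onset * config.fs))
        rec.data[ch, i0 : i0 + len(w)] += w
        occupied[ch].append((onset, offset))
        truth.events.append(GroundTruthEvent(kind, ch, onset, offset))

    truth.events.sort(key=lambda e: (e.channel, e.onset))
    return rec, truth


def write_recording(rec: EcogRecording, truth: GroundTruth, stem: str | Path) -> None:
    """Write the native recording files plus the ground-truth TSV."""
    stem = Path(stem)
    write_native(rec, stem)
    truth.write(stem.with_suffix(".events.tsv"))
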