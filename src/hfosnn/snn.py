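"""Software stand-in for the neuromorphic accumulator network.

The hardware layout is mirrored exactly: per ECoG channel, four
populations of 10 neurons each — ACC UP and ACC DN for the EEG band
(one core) and for the HFO band (another core). ACC UP populations are
wired only to UP pulses from the delta modulator, ACC DN only to DN
pulses. A core holds at most 256 neurons, so up to 8 channels (160
neurons per core, 40 per channel) fit on the 1024-neuron chip.

The neuron model is a current-based leaky integrate-and-fire unit with
an exponential synapse, simulated clock-driven with exponential-Euler
updates:

    I[t+dt] = I[t]·exp(−dt/τ_syn) + w·(pulses arriving in dt)
    V[t+dt] = V[t]·exp(−dt/τ_mem) + (1 − exp(−dt/τ_mem))·g·I[t+dt]

with firing at ``V ≥ threshold``, reset, and an absolute refractory
period. Analog device mismatch is emulated by jittering every parameter
independently per neuron around the core-shared mean with a coefficient
of variation up to 20 %, frozen at build time. This heterogeneity is a
feature, not noise: identical input drives decorrelated spike trains
across a population, which is what the downstream detection rules rely
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .adm import PulseStream

__all__ = [
    "POP_SIZE",
    "NEURONS_PER_CHANNEL",
    "CORE_CAPACITY",
    "CHIP_CAPACITY",
    "MAX_CHANNELS",
    "BANDS",
    "POPS",
    "NeuronParams",
    "MismatchModel",
    "Network",
    "SpikeRaster",
    "build_network",
    "simulate",
    "neuron_utilization",
]

POP_SIZE = 10
NEURONS_PER_CHANNEL = 40  # 2 bands x 2 populations x 10 neurons
CORE_CAPACITY = 256
CHIP_CAPACITY = 1024
MAX_CHANNELS = 8
BANDS = ("EEG", "HFO")
POPS = ("ACC_UP", "ACC_DN")
_PARAM_NAMES = (
    "membrane_tau",
    "synapse_tau",
    "threshold",
    "reset",
    "refractory",
    "input_weight",
    "gain",
)


@dataclass(frozen=True)
class NeuronParams:
    """Core-shared mean parameters of the accumulator neurons.

    ``membrane_tau`` / ``synapse_tau`` are in seconds, ``threshold`` /
    ``reset`` / ``input_weight`` in dimensionless membrane units
    (threshold fixed at 1 by convention), ``refractory`` in seconds and
    ``gain`` dimensionless. The defaults below are the shipped operating
    points for the two cores; they make a population integrate a dense
    pulse packet to threshold while staying quiet on baseline pulse
    rates, and the refractory period enforces the sparse one-spike-per-
    event regime the evolutionary tuning targets.
    """

    membrane_tau: float
    synapse_tau: float
    threshold: float = 1.0
    reset: float = 0.0
    refractory: float = 0.030
    input_weight: float = 0.1
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.membrane_tau <= 0 or self.synapse_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed reset")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _PARAM_NAMES}

    def with_updates(self, **kw: float) -> "NeuronParams":
        return replace(self, **kw)


# Shipped operating points (see docs/methods.md for the calibration story).
DEFAULT_HFO_PARAMS = NeuronParams(
    membrane_tau=0.010, synapse_tau=0.004, refractory=0.030, input_weight=0.55, gain=1.0
)
DEFAULT_EEG_PARAMS = NeuronParams(
    membrane_tau=0.020, synapse_tau=0.010, refractory=0.100, input_weight=0.5, gain=1.0
)


#: Relative mismatch sensitivity per parameter. Device mismatch is
#: dominated by the sub-threshold bias-current circuits that set time
#: constants and synaptic weights; the spiking comparator is a much
#: better-matched structure, so the effective threshold (and the gain
#: stage) vary considerably less than the biases do.
MISMATCH_SENSITIVITY: dict[str, float] = {
    "membrane_tau": 1.0,
    "synapse_tau": 1.0,
    "input_weight": 1.0,
    "refractory": 1.0,
    "gain": 0.5,
    "threshold": 0.25,
    "reset": 0.0,
}


@dataclass(frozen=True)
class MismatchModel:
    """Fabrication-mismatch emulation: multiplicative Gaussian jitter.

    ``cv`` is the coefficient of variation of the most mismatch-prone
    parameters (the bias-current-controlled time constants and weights,
    up to 20 %); each parameter's effective cv is scaled by
    :data:`MISMATCH_SENSITIVITY`.
    """

    cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cv <= 0.5:
            raise ValueError("cv must lie in [0, 0.5]")

    def cv_for(self, param: str) -> float:
        return self.cv * MISMATCH_SENSITIVITY.get(param, 1.0)


@dataclass
class Network:
    """A built network: per-neuron parameter arrays plus the chip layout.

    Neurons are indexed globally ``0 .. P−1``; companion arrays map each
    neuron to its channel, band (0=EEG, 1=HFO), population (0=ACC UP,
    1=ACC DN) and within-population unit index.
    """

    channels: list[str]
    params: dict[str, np.ndarray]
    channel_idx: np.ndarray
    band_idx: np.ndarray
    pop_idx: np.ndarray
    unit_idx: np.ndarray
    mean_params: dict[str, NeuronParams] = field(default_factory=dict)
    mismatch: MismatchModel = field(default_factory=MismatchModel)

    @property
    def n_neurons(self) -> int:
        return len(self.channel_idx)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def population_mask(self, channel: int, band: int, pop: int) -> np.ndarray:
        return (
            (self.channel_idx == channel) & (self.band_idx == band) & (self.pop_idx == pop)
        )


def build_network(
    n_channels: int,
    eeg_params: NeuronParams = DEFAULT_EEG_PARAMS,
    hfo_params: NeuronParams = DEFAULT_HFO_PARAMS,
    mismatch: MismatchModel = MismatchModel(),
    channels: list[str] | None = None,
) -> Network:
    """Instantiate the chip layout with mismatch-jittered neurons.

    Each neuron's parameters are the core-shared mean times
    ``1 + N(0, cv)``, truncated (re-drawn) to stay positive; the draw is
    deterministic given the mismatch seed.
    """
    if not 1 <= n_channels <= MAX_CHANNELS:
        raise ValueError(f"n_channels must lie in 1..{MAX_CHANNELS} (chip capacity)")
    if channels is None:
        channels = [f"CH{c + 1:02d}" for c in range(n_channels)]
    if len(channels) != n_channels:
        raise ValueError("one label per channel required")

    P = NEURONS_PER_CHANNEL * n_channels
    ch_idx = np.empty(P, dtype=np.int16)
    band_idx = np.empty(P, dtype=np.int8)
    pop_idx = np.empty(P, dtype=np.int8)
    unit_idx = np.empty(P, dtype=np.int16)
    i = 0
    for ch in range(n_channels):
        for band in range(2):
            for pop in range(2):
                for unit in range(POP_SIZE):
                    ch_idx[i], band_idx[i], pop_idx[i], unit_idx[i] = ch, band, pop, unit
                    i += 1

    rng = np.random.default_rng(mismatch.seed)
    means = {"EEG": eeg_params, "HFO": hfo_params}
    params = {name: np.empty(P) for name in _PARAM_NAMES}
    for name in _PARAM_NAMES:
        mean_vec = np.where(
            band_idx == 0, getattr(eeg_params, name), getattr(hfo_params, name)
        ).astype(np.float64)
        cv = mismatch.cv_for(name)
        factor = 1.0 + cv * rng.standard_normal(P)
        # re-draw any factor that would flip a positive parameter's sign
        bad = (factor <= 0.05) & (mean_vec > 0)
        while np.any(bad):
            factor[bad] = 1.0 + cv * rng.standard_normal(int(bad.sum()))
            bad = (factor <= 0.05) & (mean_vec > 0)
        params[name] = mean_vec * factor

    return Network(
        channels=list(channels),
        params=params,
        channel_idx=ch_idx,
        band_idx=band_idx,
        pop_idx=pop_idx,
        unit_idx=unit_idx,
        mean_params=means,
        mismatch=mismatch,
    )


def neuron_utilization(n_channels: int) -> float:
    """Fraction of the 1024-neuron chip used by ``n_channels`` channels."""
    if not 0 <= n_channels <= MAX_CHANNELS:
        raise ValueError(f"n_channels must lie in 0..{MAX_CHANNELS}")
    return NEURONS_PER_CHANNEL * n_channels / CHIP_CAPACITY


@dataclass
class SpikeRaster:
    """Timestamped spikes tagged (channel, band, population, unit)."""

    times: np.ndarray
    channel_idx: np.ndarray
    band_idx: np.ndarray
    pop_idx: np.ndarray
    unit_idx: np.ndarray
    channels: list[str]
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        for name in ("channel_idx", "band_idx", "pop_idx", "unit_idx"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            for name in ("times", "channel_idx", "band_idx", "pop_idx", "unit_idx"):
                setattr(self, name, getattr(self, name)[order])

    def __len__(self) -> int:
        return len(self.times)

    def mask(
        self,
        channel: int | None = None,
        band: int | str | None = None,
        pop: int | str | None = None,
    ) -> np.ndarray:
        m = np.ones(len(self.times), dtype=bool)
        if channel is not None:
            m &= self.channel_idx == channel
        if band is not None:
            m &= self.band_idx == (BANDS.index(band) if isinstance(band, str) else band)
        if pop is not None:
            m &= self.pop_idx == (POPS.index(pop) if isinstance(pop, str) else pop)
        return m

    def select(self, **kw) -> "SpikeRaster":
        m = self.mask(**kw)
        return SpikeRaster(
            times=self.times[m],
            channel_idx=self.channel_idx[m],
            band_idx=self.band_idx[m],
            pop_idx=self.pop_idx[m],
            unit_idx=self.unit_idx[m],
            channels=self.channels,
            duration=self.duration,
        )

    def per_neuron_counts(self, network: Network) -> np.ndarray:
        """N_i for every neuron of the network (zeros included)."""
        counts = np.zeros(network.n_neurons, dtype=np.int64)
        key_r = ((self.channel_idx.astype(np.int64) * 2 + self.band_idx) * 2 + self.pop_idx
                 ) * POP_SIZE + self.unit_idx
        key_n = ((network.channel_idx.astype(np.int64) * 2 + network.band_idx) * 2
                 + network.pop_idx) * POP_SIZE + network.unit_idx
        lookup = {int(k): i for i, k in enumerate(key_n)}
        for k in key_r:
            counts[lookup[int(k)]] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "channel": [self.channels[c] for c in self.channel_idx],
                "band": [BANDS[b] for b in self.band_idx],
                "population": [POPS[p] for p in self.pop_idx],
                "neuron_id": self.unit_idx,
            }
        )


@njit(cache=True)
def _lif_population(
    pulse_steps, n_steps, dt, tau_m, tau_s, thr, reset, refr_steps, w, gain,
    out_steps, out_unit,
):  # pragma: no cover - numba kernel
    K = tau_m.size
    V = np.zeros(K)
    I = np.zeros(K)
    ok_at = np.zeros(K, dtype=np.int64)
    dec_m = np.exp(-dt / tau_m)
    dec_s = np.exp(-dt / tau_s)
    cap = out_steps.size
    count = 0
    p = 0
    n_pulses = pulse_steps.size
    for step in range(n_steps):
        k = 0
        while p < n_pulses and pulse_steps[p] == step:
            k += 1
            p += 1
        for j in range(K):
            I[j] = I[j] * dec_s[j] + k * w[j]
            if step < ok_at[j]:
                V[j] = reset[j]
                continue
            V[j] = V[j] * dec_m[j] + (1.0 - dec_m[j]) * gain[j] * I[j]
            if V[j] >= thr[j]:
                if count < cap:
                    out_steps[count] = step
                    out_unit[count] = j
                count += 1
                V[j] = reset[j]
                ok_at[j] = step + refr_steps[j]
    return count


def _run_population(pulse_steps, n_steps, dt, p_arrays) -> tuple[np.ndarray, np.ndarray]:
    cap = max(64, 4 * len(pulse_steps) + 16 * len(p_arrays["membrane_tau"]))
    while True:
        out_steps = np.empty(cap, dtype=np.int64)
        out_unit = np.empty(cap, dtype=np.int64)
        count = _lif_population(
            pulse_steps, n_steps, dt,
            p_arrays["membrane_tau"], p_arrays["synapse_tau"], p_arrays["threshold"],
            p_arrays["reset"],
            np.maximum(np.round(p_arrays["refractory"] / dt), 1).astype(np.int64),
            p_arrays["input_weight"], p_arrays["gain"],
            out_steps, out_unit,
        )
        if count <= cap:
            return out_steps[:count], out_unit[:count]
        cap = count + 64


def simulate(
    network: Network,
    pulse_streams: list[PulseStream],
    dt: float = 1e-4,
    duration: float | None = None,
) -> SpikeRaster:
    """Clock-driven simulation of the whole network on ADM pulse input.

    Each pulse stream is routed to the matching channel/band: its UP
    pulses to the ACC UP population, its DN pulses to ACC DN. Streams
    for channels the network does not know raise ``KeyError``.
    """
    min_tau = min(
        float(np.min(network.params["membrane_tau"])),
        float(np.min(network.params["synapse_tau"])),
    )
    if dt >= min_tau / 10:
        raise ValueError(
            f"dt={dt} too coarse for time constants down to {min_tau:.4g} s; "
            "need dt < min(tau)/10"
        )
    if duration is None:
        if not pulse_streams:
            raise ValueError("need pulse streams or an explicit duration")
        duration = max(s.n_samples / s.fs for s in pulse_streams)
    n_steps = int(round(duration / dt))

    t_all, ch_all, band_all, pop_all, unit_all = [], [], [], [], []
    for stream in pulse_streams:
        if stream.channel:
            if stream.channel not in network.channels:
                raise KeyError(f"channel {stream.channel!r} not in network")
            ch = network.channels.index(stream.channel)
        else:
            ch = 0
        band = BANDS.index(stream.band)
        for pop, polarity in ((0, 1), (1, -1)):
            pulse_times = stream.select(polarity)
            pulse_steps = np.round(pulse_times / dt).astype(np.int64)
            pulse_steps = np.sort(pulse_steps[pulse_steps < n_steps])
            mask = network.population_mask(ch, band, pop)
            if not np.any(mask):
                continue
            p_arrays = {k: v[mask] for k, v in network.params.items()}
            steps, units = _run_population(pulse_steps, n_steps, dt, p_arrays)
            t_all.append(steps * dt)
            ch_all.append(np.full(len(steps), ch, dtype=np.int16))
            band_all.append(np.full(len(steps), band, dtype=np.int8))
            pop_all.append(np.full(len(steps), pop, dtype=np.int8))
            unit_all.append(units.astype(np.int16))

    if t_all:
        times = np.concatenate(t_all)
        order = np.argsort(times, kind="stable")
        raster = SpikeRaster(
            times=times[order],
            channel_idx=np.concatenate(ch_all)[order],
            band_idx=np.concatenate(band_all)[order],
            pop_idx=np.concatenate(pop_all)[order],
            unit_idx=np.concatenate(unit_all)[order],
            channels=list(network.channels),
            duration=duration,
        )
    else:
        raster = SpikeRaster(
            times=np.empty(0), channel_idx=np.empty(0, np.int16),
            band_idx=np.empty(0, np.int8), pop_idx=np.empty(0, np.int8),
            unit_idx=np.empty(0, np.int16), channels=list(network.channels),
            duration=duration,
        )
    return raster


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    """Spike raster CSV: time_s, channel, band, population, neuron_id."""
    df = raster.to_frame()
    df["time_s"] = [repr(float(t)) for t in df["time_s"]]
    df.to_csv(path, index=False)


def read_raster(path: str | Path, duration: float | None = None) -> SpikeRaster:
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) and (df["neuron_id"] < 0).any():
        bad = int(np.argmax(df["neuron_id"].to_numpy() < 0)) + 2
        raise ValueError(f"{path}:{bad}: negative neuron id")
    channels = sorted(set(df["channel"])) if len(df) else []
    times = df["time_s"].to_numpy(dtype=np.float64) if len(df) else np.empty(0)
    return SpikeRaster(
        times=times,
        channel_idx=np.array([channels.index(c) for c in df["channel"]], dtype=np.int16),
        band_idx=np.array([BANDS.index(b) for b in df["band"]], dtype=np.int8),
        pop_idx=np.array([POPS.index(p) for p in df["population"]], dtype=np.int8),
        unit_idx=df["neuron_id"].to_numpy(dtype=np.int16) if len(df) else np.empty(0, np.int16),
        channels=channels,
        duration=duration if duration is not None else (float(times[-1]) if len(times) else 0.0),
    )
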