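"""Derivative-free evolutionary tuning of the core-shared neuron biases.

The optimization target is *sparse temporal coding*: after tuning, each
accumulator neuron should spike approximately once, shortly after the
epileptiform pattern it signals, and stay silent otherwise. A single
"tuning snippet" suffices: a short stretch of pulse-encoded signal split
into an IN period (during and shortly after the pattern) and two OUT
periods (before, and long after).

Each neuron is scored

    score_i = −α·|spikes_IN − 1| + β·(spikes_IN − spikes_OUT),   α > β > 0

whose unique maximum β is attained at exactly one IN spike and no OUT
spikes. The population score combines the mean neuron score with the
fraction of neurons that spiked at all (a silent population must never
outrank a fully participating one).

The optimizer itself is a shrinking-volume elitist random search:
sample parameter configurations uniformly inside the current volumes
(log-uniformly for time constants and the refractory period), simulate
the snippet, score, keep the elites, recenter the volumes on them and
shrink. The best score seen is monotonically non-decreasing by
construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .adm import PulseStream
from .snn import Network, SpikeRaster, simulate

__all__ = [
    "TuningSnippet",
    "ScoreWeights",
    "EvolutionConfig",
    "EvolutionResult",
    "neuron_score",
    "population_score",
    "evolve",
    "DEFAULT_BOUNDS",
    "LOG_PARAMS",
]

LOG_PARAMS = frozenset({"membrane_tau", "synapse_tau", "refractory"})

# Tunable set: the "biases" exposed for optimization.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "membrane_tau": (0.002, 0.050),
    "synapse_tau": (0.001, 0.030),
    "threshold": (0.5, 2.0),
    "input_weight": (0.005, 0.5),
    "gain": (0.5, 2.0),
    "refractory": (0.005, 0.200),
}


@dataclass(frozen=True)
class ScoreWeights:
    """α and β of the neuron score; validity requires α > β > 0."""

    alpha: float = 2.0
    beta: float = 1.0
    gamma: float = 1.0  # weight of the non-spiking-fraction penalty

    def __post_init__(self) -> None:
        if not self.alpha > self.beta > 0:
            raise ValueError("weights must satisfy alpha > beta > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class TuningSnippet:
    """A pulse-encoded snippet with IN / OUT period annotations."""

    pulses: PulseStream
    in_interval: tuple[float, float]
    out_intervals: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        ivs = [self.in_interval, *self.out_intervals]
        for a, b in ivs:
            if not a < b:
                raise ValueError("intervals must have start < end")
        for i, (a1, b1) in enumerate(ivs):
            for a2, b2 in ivs[i + 1 :]:
                if max(a1, a2) < min(b1, b2):
                    raise ValueError("IN and OUT intervals must be disjoint")

    @property
    def duration(self) -> float:
        return self.pulses.n_samples / self.pulses.fs

    @classmethod
    def around_pattern(
        cls,
        pulses: PulseStream,
        pattern_onset: float,
        pattern_offset: float,
        in_tail: float = 0.050,
        out_margin: float = 0.100,
        out_duration: float | None = None,
    ) -> "TuningSnippet":
        """IN = pattern + ``in_tail``; OUT = everything before and after,
        trimmed ``out_margin`` from the IN edges (optionally capped at
        ``out_duration`` seconds per window)."""
        duration = pulses.n_samples / pulses.fs
        in_iv = (pattern_onset, min(pattern_offset + in_tail, duration))
        o1b = max(pattern_onset - out_margin, 2e-3)
        o1a = 1e-3 if out_duration is None else max(o1b - out_duration, 1e-3)
        o2a = min(in_iv[1] + out_margin, duration - 2e-3)
        o2b = duration if out_duration is None else min(o2a + out_duration, duration)
        return cls(pulses=pulses, in_interval=in_iv, out_intervals=((o1a, o1b), (o2a, o2b)))

    def count_spikes(self, raster: SpikeRaster, band: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-neuron (spikes_IN, spikes_OUT) over the snippet, 20 neurons per band."""
        sub = raster.select(band=band)
        key = sub.pop_idx.astype(np.int64) * 10 + sub.unit_idx
        n_in = np.zeros(20, dtype=np.int64)
        n_out = np.zeros(20, dtype=np.int64)
        a, b = self.in_interval
        in_mask = (sub.times >= a) & (sub.times < b)
        out_mask = np.zeros(len(sub.times), dtype=bool)
        for oa, ob in self.out_intervals:
            out_mask |= (sub.times >= oa) & (sub.times < ob)
        np.add.at(n_in, key[in_mask], 1)
        np.add.at(n_out, key[out_mask], 1)
        return n_in, n_out


def neuron_score(spikes_in: int, spikes_out: int, weights: ScoreWeights) -> float:
    """−α|spikes_IN − 1| + β(spikes_IN − spikes_OUT)."""
    if spikes_in < 0 or spikes_out < 0:
        raise ValueError("spike counts must be >= 0")
    return -weights.alpha * abs(spikes_in - 1) + weights.beta * (spikes_in - spikes_out)


def population_score(
    neuron_scores: np.ndarray, fraction_spiking: float, gamma: float = 1.0
) -> float:
    """mean(neuron scores) − γ·(1 − fraction of neurons that spiked)."""
    neuron_scores = np.asarray(neuron_scores, dtype=np.float64)
    if neuron_scores.size == 0:
        raise ValueError("need at least one neuron score")
    if not 0 <= fraction_spiking <= 1:
        raise ValueError("fraction_spiking must lie in [0, 1]")
    return float(np.mean(neuron_scores)) - gamma * (1.0 - fraction_spiking)


@dataclass(frozen=True)
class EvolutionConfig:
    samples_per_iteration: int = 20
    n_elites: int = 4
    n_iterations: int = 10
    shrink_factor: float = 0.7
    seed: int = 0
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 < self.shrink_factor <= 1:
            raise ValueError("shrink_factor must lie in (0, 1]")
        if self.n_elites < 1 or self.samples_per_iteration < self.n_elites:
            raise ValueError("need samples_per_iteration >= n_elites >= 1")


@dataclass
class EvolutionResult:
    best_params: dict[str, float]
    best_score: float
    trace: list[float]
    history: list[dict]

    def write_report(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "best_params": self.best_params,
                    "best_score": self.best_score,
                    "best_score_trace": self.trace,
                    "iterations": self.history,
                },
                indent=1,
            )
        )


def _to_sampling_space(name: str, value: float) -> float:
    return math.log(value) if name in LOG_PARAMS else value


def _from_sampling_space(name: str, value: float) -> float:
    return math.exp(value) if name in LOG_PARAMS else value


def evolve(
    network_builder: Callable[[dict[str, float]], Network],
    snippet: TuningSnippet,
    bounds: dict[str, tuple[float, float]] | None = None,
    config: EvolutionConfig = EvolutionConfig(),
) -> EvolutionResult:
    """Optimize core-shared parameters for sparse temporal coding.

    ``network_builder`` maps a parameter dict (keys a subset of the
    tunable set) to a built network; the snippet's band selects which 20
    neurons are scored. A configuration whose simulation raises is
    scored −inf and the run continues.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    for name, (lo, hi) in bounds.items():
        ok = math.isfinite(lo) and math.isfinite(hi) and lo < hi
        if name in LOG_PARAMS:
            ok = ok and lo > 0
        if not ok:
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
    names = sorted(bounds)
    lo_s = np.array([_to_sampling_space(n, bounds[n][0]) for n in names])
    hi_s = np.array([_to_sampling_space(n, bounds[n][1]) for n in names])

    rng = np.random.default_rng(config.seed)
    band = snippet.pulses.band
    # volumes: list of (center, half_width) in sampling space
    volumes = [((lo_s + hi_s) / 2, (hi_s - lo_s) / 2)]
    elite_pool: list[tuple[float, np.ndarray, dict[str, float]]] = []
    best_score = -math.inf
    best_params: dict[str, float] = {}
    trace: list[float] = []
    history: list[dict] = []

    for iteration in range(config.n_iterations):
        samples = []
        for k in range(config.samples_per_iteration):
            center, half = volumes[k % len(volumes)]
            s = rng.uniform(center - half, center + half)
            s = np.clip(s, lo_s, hi_s)
            samples.append(s)

        scored = []
        for s in samples:
            params = {n: _from_sampling_space(n, v) for n, v in zip(names, s)}
            try:
                net = network_builder(params)
                raster = simulate(
                    net, [snippet.pulses], dt=config.dt, duration=snippet.duration
                )
                n_in, n_out = snippet.count_spikes(raster, band)
                scores = np.array(
                    [neuron_score(int(a), int(b), config.weights) for a, b in zip(n_in, n_out)]
                )
                frac = float(np.mean((n_in + n_out) > 0))
                score = population_score(scores, frac, config.weights.gamma)
            except Exception:
                score = -math.inf
            scored.append((score, s, params))

        # elites persist across iterations: volumes always recenter on the
        # best configurations seen so far, never on a weaker recent batch
        elite_pool.extend(scored)
        elite_pool.sort(key=lambda t: t[0], reverse=True)
        del elite_pool[config.n_elites :]
        elites = elite_pool
        if elites[0][0] > best_score:
            best_score = elites[0][0]
            best_params = elites[0][2]
        trace.append(best_score)
        history.append(
            {
                "iteration": iteration,
                "best_score": best_score,
                "iteration_best": elites[0][0],
                "iteration_best_params": elites[0][2],
            }
        )
        width = volumes[0][1] * config.shrink_factor
        volumes = [(s, width) for _, s, _ in elites]

    return EvolutionResult(
        best_params=best_params, best_score=best_score, trace=trace, history=history
    )
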