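"""Signal reconstruction from sparse spike rasters with full-FORCE.

The point of this module is validation: if a continuous ECoG trace can
be reconstructed from the accumulator network's sparse spikes alone,
the spike encoding demonstrably preserves signal morphology.

Training follows the target-based full-FORCE recipe. A fixed randomly
connected rate network (*teacher*) is driven by the smoothed spike
inputs **and** the target trace (as a hint input); its internal drive
combines input and output information. A second network of the same
size (*student*) receives only the spike inputs, and its recurrent
weights are adapted online with recursive least squares (RLS) so its
internal drive matches the teacher's. A linear readout then extracts
the target trace from the student's activity. At inference the student
and readout never see the target — ``reconstruct`` takes only spikes.

Network dynamics (rate units): ``τ ẋ = −x + J·tanh(x) + W_in·s(t)
[+ W_hint·y(t) for the teacher]``, integrated with exponential Euler at
``dt``. Spike trains enter through an exponential smoothing kernel
(20 ms) with one input channel per neuron of the spiking network.

Snippet selection mirrors the evaluation protocol: only segments where
both ACC UP and ACC DN fired and the total spike span is ≤ 500 ms are
kept, padded by a margin, split chronologically into train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detection import DetectionRules, segment_eoi, smooth_activity
from .snn import SpikeRaster

__all__ = [
    "RnnConfig",
    "RlsConfig",
    "Snippet",
    "SnippetSet",
    "FullForceModel",
    "select_snippets",
    "train_full_force",
    "reconstruct",
    "evaluate_reconstruction",
]


@dataclass(frozen=True)
class RnnConfig:
    n_units: int = 300
    g: float = 0.9
    tau: float = 0.010  # s
    dt: float = 0.001  # s
    input_scale: float = 4.0
    hint_scale: float = 0.3
    smoothing_tau: float = 0.020  # s, spike input kernel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 10:
            raise ValueError("n_units must be >= 10")
        if not self.dt < self.tau:
            raise ValueError("dt must be smaller than the unit time constant")


@dataclass(frozen=True)
class RlsConfig:
    lam: float = 1.0  # initial inverse-correlation scale
    update_interval: int = 2  # steps between RLS updates
    n_passes: int = 3
    #: readout shrinkage relative to the mean diagonal of the state
    #: covariance; enough that the readout generalizes across snippets
    #: instead of memorizing training states, while keeping a normal
    #: train/test fit gap
    readout_ridge: float = 1e-4

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")


@dataclass
class Snippet:
    """One (spike inputs, target trace) segment on the RNN time grid."""

    inputs: np.ndarray  # (n_in, n_steps) smoothed spike channels
    target: np.ndarray  # (n_steps,)
    start: float
    split: str = "train"
    snippet_id: int = 0


@dataclass
class SnippetSet:
    snippets: list[Snippet] = field(default_factory=list)

    def split(self, which: str) -> list[Snippet]:
        return [s for s in self.snippets if s.split == which]

    def __len__(self) -> int:
        return len(self.snippets)


def _smoothed_inputs(
    raster: SpikeRaster, channel: int, band: str, t0: float, t1: float, cfg: RnnConfig
) -> np.ndarray:
    """Per-neuron exponentially smoothed spike trains on the dt grid."""
    sub = raster.select(channel=channel, band=band)
    n_steps = int(round((t1 - t0) / cfg.dt))
    n_in = 20  # 2 populations x 10 units
    out = np.zeros((n_in, n_steps))
    m = (sub.times >= t0) & (sub.times < t1)
    keys = (sub.pop_idx[m] * 10 + sub.unit_idx[m]).astype(np.int64)
    steps = np.floor((sub.times[m] - t0) / cfg.dt).astype(np.int64)
    np.add.at(out, (keys, np.minimum(steps, n_steps - 1)), 1.0)
    decay = np.exp(-cfg.dt / cfg.smoothing_tau)
    for i in range(1, n_steps):
        out[:, i] += out[:, i - 1] * decay
    return out


def select_snippets(
    raster: SpikeRaster,
    signal: np.ndarray,
    fs: float,
    channel: int = 0,
    band: str = "EEG",
    rnn_config: RnnConfig = RnnConfig(),
    max_span: float = 0.500,
    margin: float = 0.100,
    train_boundary: float | None = None,
    rules: DetectionRules = DetectionRules(),
) -> SnippetSet:
    """Qualifying activity segments as (inputs, target) snippets.

    A segment qualifies when both ACC UP and ACC DN fired and the spike
    span is ≤ ``max_span``. ``train_boundary`` (seconds) splits
    chronologically; by default the first quarter of the recording is
    the train set.
    """
    import warnings

    signal = np.asarray(signal, dtype=np.float64)
    duration = len(signal) / fs
    if train_boundary is None:
        train_boundary = duration / 4
    trace = smooth_activity(raster, channel, band, rules, duration)
    sub = raster.select(channel=channel, band=band)
    snippets = []
    sid = 0
    for seg in segment_eoi(trace):
        if not (seg["has_up"] and seg["has_dn"]):
            continue
        m = (sub.times >= seg["start"]) & (sub.times < seg["end"])
        span = float(sub.times[m].max() - sub.times[m].min())
        if span > max_span:
            continue
        t0 = max(float(sub.times[m].min()) - margin, 0.0)
        t1 = min(float(sub.times[m].max()) + margin, duration)
        step = int(round(rnn_config.dt * fs))
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        target = signal[i0:i1:step]
        inputs = _smoothed_inputs(raster, channel, band, t0, t0 + len(target) * rnn_config.dt,
                                  rnn_config)
        n = min(inputs.shape[1], len(target))
        if n < 10:
            continue
        snippets.append(
            Snippet(
                inputs=inputs[:, :n], target=target[:n], start=t0,
                split="train" if t0 < train_boundary else "test", snippet_id=sid,
            )
        )
        sid += 1
    if not snippets:
        warnings.warn("no qualifying snippets found", stacklevel=2)
    return SnippetSet(snippets)


@dataclass
class FullForceModel:
    config: RnnConfig
    J_teacher: np.ndarray
    J_student: np.ndarray
    W_in: np.ndarray
    W_hint: np.ndarray
    readout: np.ndarray | None = None
    target_scale: float = 1.0
    mismatch_trace: list[float] = field(default_factory=list)

    @property
    def trained(self) -> bool:
        return self.readout is not None

    def save(self, path: str | Path) -> None:
        np.savez(
            path, J_teacher=self.J_teacher, J_student=self.J_student, W_in=self.W_in,
            W_hint=self.W_hint, readout=self.readout if self.readout is not None else [],
            target_scale=self.target_scale,
            config=np.array(
                [self.config.n_units, self.config.g, self.config.tau, self.config.dt,
                 self.config.input_scale, self.config.hint_scale,
                 self.config.smoothing_tau, self.config.seed]
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FullForceModel":
        z = np.load(path, allow_pickle=False)
        c = z["config"]
        cfg = RnnConfig(
            n_units=int(c[0]), g=float(c[1]), tau=float(c[2]), dt=float(c[3]),
            input_scale=float(c[4]), hint_scale=float(c[5]), smoothing_tau=float(c[6]),
            seed=int(c[7]),
        )
        readout = z["readout"]
        return cls(
            config=cfg, J_teacher=z["J_teacher"], J_student=z["J_student"],
            W_in=z["W_in"], W_hint=z["W_hint"],
            readout=None if readout.size == 0 else readout,
            target_scale=float(z["target_scale"]),
        )


def _init_model(cfg: RnnConfig, n_in: int) -> FullForceModel:
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_units
    J = rng.standard_normal((N, N)) * (cfg.g / np.sqrt(N))
    W_in = rng.uniform(-1, 1, size=(N, n_in)) * cfg.input_scale
    W_hint = rng.uniform(-1, 1, size=(N, 1)) * cfg.hint_scale
    return FullForceModel(
        config=cfg, J_teacher=J, J_student=J.copy(), W_in=W_in, W_hint=W_hint
    )


def _run_net(
    J: np.ndarray, W_in: np.ndarray, inputs: np.ndarray, cfg: RnnConfig,
    hint: np.ndarray | None = None, W_hint: np.ndarray | None = None,
    record_drive: bool = False,
):
    """Integrate τẋ = −x + J·r + W_in·s (+ hint); return rates (and drives)."""
    N = J.shape[0]
    n_steps = inputs.shape[1]
    a = cfg.dt / cfg.tau
    x = np.zeros(N)
    rates = np.empty((n_steps, N))
    drives = np.empty((n_steps, N)) if record_drive else None
    for t in range(n_steps):
        r = np.tanh(x)
        drive = J @ r
        if hint is not None:
            drive = drive + (W_hint[:, 0] * hint[t])
        if record_drive:
            drives[t] = drive
        x = (1 - a) * x + a * (drive + W_in @ inputs[:, t])
        rates[t] = np.tanh(x)
    return (rates, drives) if record_drive else rates


def train_full_force(
    snippets_train: list[Snippet],
    rnn_config: RnnConfig = RnnConfig(),
    rls_config: RlsConfig = RlsConfig(),
) -> FullForceModel:
    """Teacher/student training with RLS, then a ridge readout.

    The student's recurrent matrix is adapted so its internal drive
    matches the teacher's hint-informed drive; the mean squared
    student–teacher mismatch per pass is recorded in
    ``model.mismatch_trace``. Raises on divergence (non-finite state).
    """
    if not snippets_train:
        raise ValueError("training set is empty")
    n_in = snippets_train[0].inputs.shape[0]
    model = _init_model(rnn_config, n_in)
    cfg = rnn_config
    N = cfg.n_units
    scale = float(np.std(np.concatenate([s.target for s in snippets_train]))) or 1.0
    model.target_scale = scale

    # teacher drives per snippet (fixed; computed once)
    teacher = []
    for s in snippets_train:
        y = s.target / scale
        _, drives = _run_net(
            model.J_teacher, model.W_in, s.inputs, cfg, hint=y, W_hint=model.W_hint,
            record_drive=True,
        )
        teacher.append(drives)

    P = np.eye(N) / rls_config.lam
    Js = model.J_student
    a = cfg.dt / cfg.tau
    for pass_i in range(rls_config.n_passes):
        sq_err = 0.0
        n_err = 0
        for s, drives_T in zip(snippets_train, teacher):
            x = np.zeros(N)
            for t in range(s.inputs.shape[1]):
                r = np.tanh(x)
                drive_S = Js @ r
                x = (1 - a) * x + a * (drive_S + model.W_in @ s.inputs[:, t])
                err = drive_S - drives_T[t]
                sq_err += float(err @ err)
                n_err += 1
                if t % rls_config.update_interval == 0:
                    Pr = P @ r
                    denom = 1.0 + float(r @ Pr)
                    P -= np.outer(Pr, Pr) / denom
                    Js -= np.outer(err, Pr) / denom
            if not np.all(np.isfinite(x)) or not np.all(np.isfinite(Js)):
                raise FloatingPointError("RLS diverged: non-finite student state")
        model.mismatch_trace.append(sq_err / max(n_err, 1))

    # readout: ridge regression student rates -> normalized target
    states = []
    targets = []
    for s in snippets_train:
        rates = _run_net(Js, model.W_in, s.inputs, cfg)
        states.append(rates)
        targets.append(s.target / scale)
    R = np.concatenate(states)
    y = np.concatenate(targets)
    gram = R.T @ R
    ridge = rls_config.readout_ridge * np.trace(gram) / N
    model.readout = np.linalg.solve(gram + ridge * np.eye(N), R.T @ y)
    model.J_student = Js
    return model


def reconstruct(model: FullForceModel, inputs: np.ndarray) -> np.ndarray:
    """Run the student on spike inputs only and apply the readout."""
    if not model.trained:
        raise ValueError("model has no trained readout")
    rates = _run_net(model.J_student, model.W_in, np.atleast_2d(inputs), model.config)
    return (rates @ model.readout) * model.target_scale


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_reconstruction(
    snippet_set: SnippetSet, model: FullForceModel
) -> dict[str, object]:
    """Per-snippet Pearson r between target and reconstruction; medians per split.

    Snippets with a constant target are flagged and excluded from the
    medians.
    """
    rows = []
    flagged = []
    for s in snippet_set.snippets:
        r = pearson(s.target, reconstruct(model, s.inputs))
        if np.isnan(r):
            flagged.append(s.snippet_id)
            continue
        rows.append({"snippet_id": s.snippet_id, "split": s.split, "r": r})
    medians = {}
    for which in ("train", "test"):
        vals = [row["r"] for row in rows if row["split"] == which]
        medians[which] = float(np.median(vals)) if vals else float("nan")
    return {"per_snippet": rows, "median": medians, "flagged": flagged}
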