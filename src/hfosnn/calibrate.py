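"""Session-calibration helpers built on the synthetic generator.

The optimizer needs one tuning snippet per pattern class
and the reconstruction validator needs a recording with enough events
to harvest snippets from; this module fabricates both from a pipeline
config, so the CLI, the examples and the test-suite share one recipe.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import preprocessing, snn, synthetic
from .config import PipelineConfig
from .evolution import TuningSnippet
from .pipeline import tune_and_encode_channel
from .reconstruction import (
    RlsConfig, RnnConfig, evaluate_reconstruction, select_snippets, train_full_force,
)

__all__ = ["make_tuning_snippet", "band_builder", "reconstruction_demo"]

_SNIPPET_DURATION = 8.0  # s: 5 s tuning baseline + pattern + tail
_PATTERN_ONSET = 6.0


def make_tuning_snippet(
    cfg: PipelineConfig, band: str, exemplar_factor: float = 3.0
) -> TuningSnippet:
    """One-pattern snippet: 6 s of baseline, then an HFO (HFO band) or an
    IED (EEG band), pulse-encoded with the session's ADM settings.

    The pattern is a *prominent exemplar* — ``exemplar_factor`` times the
    typical event amplitude — mirroring how an experimenter picks the
    clearest pattern of a session for calibration. The IN period covers
    the pattern plus a 50 ms tail (shifted by the filter group delay);
    the OUT periods are the baseline before and the stretch after.
    """
    syn = dataclasses.replace(
        cfg.synthetic, n_channels=1, duration=_SNIPPET_DURATION,
        event_counts={k: 0 for k in synthetic.EVENT_KINDS},
    )
    rec = synthetic.generate_background(syn)
    if band == "HFO":
        w = synthetic.synthesize_event_waveform(
            "hfo", syn.fs, freq=float(np.mean(syn.hfo_freq_range)),
            duration=float(np.mean(syn.hfo_duration_range)),
            amplitude=exemplar_factor * syn.hfo_amplitude,
        )
    else:
        w = synthetic.synthesize_event_waveform(
            "ied", syn.fs, duration=float(np.mean(syn.ied_duration_range)),
            amplitude=exemplar_factor * syn.ied_amplitude,
        )
    i0 = int(round(_PATTERN_ONSET * syn.fs))
    rec.data[0, i0 : i0 + len(w)] += w
    onset, offset = _PATTERN_ONSET, _PATTERN_ONSET + len(w) / syn.fs

    spec = preprocessing.FilterSpec(
        band=cfg.filter.hfo_band if band == "HFO" else cfg.filter.eeg_band,
        fs=syn.fs, order=cfg.filter.order,
    )
    filtered = preprocessing.stream_filter(rec.data[0], spec, cfg.filter.block_size)
    pulses = tune_and_encode_channel(filtered, syn.fs, band, cfg, channel="CH01")
    delay = spec.group_delay_seconds
    return TuningSnippet.around_pattern(
        pulses, pattern_onset=onset + delay, pattern_offset=offset + delay,
    )


def band_builder(cfg: PipelineConfig, band: str):
    """Callable mapping a tunable-parameter dict to a 1-channel network."""
    def build(params: dict[str, float]) -> snn.Network:
        base = cfg.snn.hfo if band == "HFO" else cfg.snn.eeg
        tuned = base.with_updates(**params)
        kwargs = {"hfo_params": tuned} if band == "HFO" else {"eeg_params": tuned}
        return snn.build_network(1, mismatch=cfg.mismatch(), channels=["CH01"], **kwargs)

    return build


def reconstruction_demo(
    cfg: PipelineConfig,
    duration: float = 120.0,
    n_events: int = 40,
    band: str = "EEG",
) -> dict:
    """Train and evaluate full-FORCE reconstruction on a synthetic session.

    Generates a 1-channel recording dense in IEDs, runs the front end
    (filter → ADM → SNN), harvests qualifying snippets, trains on the
    chronologically first quarter and evaluates per-snippet Pearson r.
    """
    syn = cfg.synthetic.with_counts(ied=n_events)
    syn = dataclasses.replace(syn, n_channels=1, duration=duration)
    rec, truth = synthetic.generate_recording(syn)

    band_t = cfg.filter.eeg_band if band == "EEG" else cfg.filter.hfo_band
    spec = preprocessing.FilterSpec(band=band_t, fs=rec.fs, order=cfg.filter.order)
    filtered = preprocessing.stream_filter(rec.data[0], spec, cfg.filter.block_size)
    pulses = tune_and_encode_channel(filtered, rec.fs, band, cfg, channel="CH01")

    network = snn.build_network(
        1, eeg_params=cfg.snn.eeg, hfo_params=cfg.snn.hfo,
        mismatch=cfg.mismatch(), channels=["CH01"],
    )
    raster = snn.simulate(network, [pulses], dt=cfg.snn.dt, duration=duration)

    rnn_cfg = dataclasses.replace(cfg.reconstruction.rnn, seed=cfg.seed)
    snippets = select_snippets(
        raster, filtered, rec.fs, channel=0, band=band, rnn_config=rnn_cfg,
        max_span=cfg.reconstruction.max_span, margin=cfg.reconstruction.margin,
    )
    train = snippets.split("train")
    model = train_full_force(train, rnn_cfg, cfg.reconstruction.rls)
    report = evaluate_reconstruction(snippets, model)
    report["n_train"] = len(train)
    report["n_test"] = len(snippets.split("test"))
    report["mismatch_trace"] = model.mismatch_trace
    report["n_pulses"] = len(pulses)
    report["n_spikes"] = len(raster)
    report["n_samples"] = int(rec.n_samples)
    return report
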