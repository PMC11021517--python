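"""End-to-end orchestration: signal → pulses → spikes → events → reports.

``run_pipeline`` chains the four processing steps on a recording (or on
a synthetic one generated from the config): band-pass filtering, ADM
threshold tuning + encoding, spiking-network simulation, and rule-based
detection, plus compression accounting. Identical config + seed yields
identical outputs at every stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adm, detection, preprocessing, snn, synthetic
from .config import PipelineConfig
from .recording import EcogRecording, write_native

logger = logging.getLogger("hfosnn")

__all__ = ["PipelineResult", "run_pipeline", "encode_recording", "score_against_truth"]


def tune_and_encode_channel(
    x: np.ndarray, fs: float, band: str, cfg: PipelineConfig, channel: str
) -> adm.PulseStream:
    """Tune δ on the initial tuning phase of one filtered channel, then encode it."""
    if band == "EEG":
        tuning = adm.TuningConfig(
            tuning_duration=cfg.adm.tuning_duration, window_len=cfg.adm.eeg_window_len,
            percentile=cfg.adm.eeg_percentile, delta_min=cfg.adm.delta_min,
        )
        refractory = cfg.adm.eeg_refractory
    else:
        tuning = adm.TuningConfig(
            tuning_duration=cfg.adm.tuning_duration, window_len=cfg.adm.hfo_window_len,
            percentile=cfg.adm.hfo_percentile, delta_min=cfg.adm.delta_min,
        )
        refractory = cfg.adm.hfo_refractory
    delta = adm.tune_threshold(x, tuning, fs)
    params = adm.AdmParams(delta=delta, refractory=refractory, band=band)
    return adm.encode(x, params, fs, channel=channel)


def encode_recording(
    bands: preprocessing.FilteredBands, cfg: PipelineConfig
) -> list[adm.PulseStream]:
    streams = []
    for band_name in ("EEG", "HFO"):
        rec = bands.band(band_name)
        for ch, label in enumerate(rec.channels):
            streams.append(
                tune_and_encode_channel(rec.data[ch], rec.fs, band_name, cfg, label)
            )
    return streams


@dataclass
class PipelineResult:
    recording: EcogRecording
    bands: preprocessing.FilteredBands
    pulses: list[adm.PulseStream]
    network: snn.Network
    raster: snn.SpikeRaster
    events: list[detection.DetectedEvent]
    rates: pd.DataFrame
    compression: dict
    truth: synthetic.GroundTruth | None = None
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def accepted_events(self) -> list[detection.DetectedEvent]:
        return detection.accepted(self.events)


def run_pipeline(
    cfg: PipelineConfig,
    recording: EcogRecording | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage in order, logging per-stage wall time.

    When ``recording`` is None a synthetic recording (with ground
    truth) is generated from ``cfg.synthetic``. With ``out_dir`` set,
    intermediate artifacts are written there.
    """
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.2fs", name, timings[name])

    truth = None
    if recording is None:
        stage("synthesize")
        recording, truth = synthetic.generate_recording(cfg.synthetic)
        done("synthesize")

    stage("filter")
    bands = preprocessing.filter_recording(
        recording, order=cfg.filter.order, block_size=cfg.filter.block_size,
        eeg_band=cfg.filter.eeg_band, hfo_band=cfg.filter.hfo_band,
    )
    done("filter")

    stage("encode")
    pulses = encode_recording(bands, cfg)
    done("encode")

    stage("simulate")
    network = snn.build_network(
        recording.n_channels, eeg_params=cfg.snn.eeg, hfo_params=cfg.snn.hfo,
        mismatch=cfg.mismatch(), channels=list(recording.channels),
    )
    raster = snn.simulate(network, pulses, dt=cfg.snn.dt, duration=recording.duration)
    done("simulate")

    stage("detect")
    events = detection.detect(raster, cfg.detection, duration=recording.duration)
    rates = detection.event_rates(
        detection.accepted(events), recording.duration, n_channels=recording.n_channels
    )
    done("detect")

    T = recording.n_samples * recording.n_channels * 2  # both band streams
    n_pulses = sum(len(p) for p in pulses)
    n_spikes = len(raster)
    compression = {
        "T": T,
        "n_up_dn": n_pulses,
        "sum_Ni": n_spikes,
        "adm_ratio": adm.compression_ratio(T, n_pulses) if n_pulses else float("inf"),
        "snn_ratio": adm.compression_ratio(T, n_spikes) if n_spikes else float("inf"),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_native(recording, out_dir / "recording")
        if truth is not None:
            truth.write(out_dir / "ground_truth.tsv")
        adm.write_pulses(pulses, out_dir / "pulses.csv")
        snn.write_raster(raster, out_dir / "raster.csv")
        detection.write_events(events, out_dir / "detections.tsv", recording.channels)
        rates.to_csv(out_dir / "rates.csv", index=False)

    return PipelineResult(
        recording=recording, bands=bands, pulses=pulses, network=network,
        raster=raster, events=events, rates=rates, compression=compression,
        truth=truth, timings=timings,
    )


def score_against_truth(
    events: list[detection.DetectedEvent],
    truth: synthetic.GroundTruth,
    pre_slack: float = 0.050,
    post_slack: float = 0.150,
) -> dict:
    """Ground-truth recovery: which injections were found, which artifacts
    were wrongly accepted.

    Detection times live in filtered/spike time (group delay + neuron
    latency after the signal event), so an injection counts as detected
    when an accepted event overlaps ``[onset − pre_slack, offset +
    post_slack]`` on its channel.
    """
    acc = detection.accepted(events)

    def overlaps(e, gt) -> bool:
        return (
            e.channel == gt.channel
            and max(e.start, gt.onset - pre_slack) < min(e.end, gt.offset + post_slack)
        )

    out: dict[str, object] = {}
    for kind in ("hfo", "ied_hfo"):
        injected = truth.of_kind(kind)
        hits = sum(1 for gt in injected if any(overlaps(e, gt) for e in acc))
        out[f"{kind}_injected"] = len(injected)
        out[f"{kind}_detected"] = hits
    n_epileptiform = out["hfo_injected"] + out["ied_hfo_injected"]
    n_hits = out["hfo_detected"] + out["ied_hfo_detected"]
    out["sensitivity"] = n_hits / n_epileptiform if n_epileptiform else float("nan")

    artefacts = truth.of_kind("step_artifact") + truth.of_kind("long_artifact")
    out["artifact_injected"] = len(artefacts)
    out["artifact_accepted"] = sum(
        1 for gt in artefacts if any(overlaps(e, gt) for e in acc)
    )

    out["false_detections"] = sum(
        1 for e in acc if not any(overlaps(e, gt) for gt in truth)
    )
    out["n_accepted"] = len(acc)
    return out
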