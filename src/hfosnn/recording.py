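"""Multichannel ECoG recording container and its native on-disk format.

The canonical on-disk representation is deliberately simple: a raw
little-endian float32 sample matrix (``.raw``) next to a JSON sidecar
carrying the sampling rate, channel labels and units. EDF files can be
*read* through :mod:`mne` when it is installed; the native format is what
the rest of the package (and the test-suite) uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EcogRecording", "write_native", "read_native", "read_edf"]


@dataclass
class EcogRecording:
    """A continuous multichannel recording, samples in microvolts.

    Attributes
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``.
    fs:
        Sampling rate in Hz.
    channels:
        One label per row of ``data``.
    units:
        Physical unit of the samples (always ``"uV"`` for data produced by
        this package).
    meta:
        Free-form montage / provenance metadata.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    units: str = "uV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError as exc:
            raise KeyError(f"unknown channel {label!r}") from exc
        return self.data[idx]


def write_native(rec: EcogRecording, path: str | Path) -> Path:
    """Write ``<path>.raw`` + ``<path>.json``; returns the sidecar path."""
    path = Path(path)
    raw_path = path.with_suffix(".raw")
    json_path = path.with_suffix(".json")
    rec.data.astype("<f4").tofile(raw_path)
    sidecar = {
        "fs": rec.fs,
        "channels": list(rec.channels),
        "units": rec.units,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "meta": rec.meta,
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return json_path


def read_native(path: str | Path) -> EcogRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".raw"), dtype=sidecar["dtype"])
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"])
    return EcogRecording(
        data=data.astype(np.float64),
        fs=sidecar["fs"],
        channels=sidecar["channels"],
        units=sidecar["units"],
        meta=sidecar.get("meta", {}),
    )


def read_edf(path: str | Path) -> EcogRecording:
    """Read an EDF file (requires the optional :mod:`mne` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires mne (pip install hfosnn[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return EcogRecording(data=data, fs=float(raw.info["sfreq"]), channels=list(raw.ch_names))
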