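"""Plain-text serialisation: recordings, averaged waveforms and spectra.

A recording ``<stem>`` is stored as three files —

* ``<stem>.csv``       sample x channel matrix, header = channel labels
* ``<stem>.events.csv``  columns ``sample,code``
* ``<stem>.json``      sidecar with rate_hz, n_samples, n_channels

The sidecar's sample/channel counts let a truncated data file be rejected
instead of silently read short.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AveragedWaveform
from .simulate import EEGRecording
from .stimulus import AmplitudeSpectrum

__all__ = [
    "write_recording",
    "read_recording",
    "write_waveform",
    "read_waveform",
    "spectrum_to_csv",
    "spectrum_from_csv",
]


def _paths(stem):
    stem = Path(stem)
    base = stem.parent / stem.name.removesuffix(".csv")
    return (
        base.with_suffix(".csv"),
        base.parent / f"{base.name}.events.csv",
        base.with_suffix(".json"),
    )


def write_recording(rec: EEGRecording, stem) -> None:
    data_p, events_p, meta_p = _paths(stem)
    data_p.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(
        data_p, index=False, float_format="%.6f"
    )
    pd.DataFrame(rec.events, columns=["sample", "code"]).to_csv(events_p, index=False)
    meta_p.write_text(
        json.dumps(
            {
                "rate_hz": rec.rate_hz,
                "n_samples": rec.n_samples,
                "n_channels": rec.n_channels,
                "channel_labels": rec.channel_labels,
            }
        )
    )


def read_recording(stem) -> EEGRecording:
    data_p, events_p, meta_p = _paths(stem)
    for p in (data_p, events_p, meta_p):
        if not p.exists():
            raise FileNotFoundError(p)
    try:
        meta = json.loads(meta_p.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed sidecar {meta_p}: {e}") from None
    df = pd.read_csv(data_p)
    if df.shape != (meta["n_samples"], meta["n_channels"]):
        raise ValueError(
            f"{data_p}: expected {meta['n_samples']} x {meta['n_channels']} "
            f"samples x channels, found {df.shape[0]} x {df.shape[1]} "
            "(truncated or corrupt file)"
        )
    if list(df.columns) != list(meta["channel_labels"]):
        raise ValueError(f"{data_p}: channel labels disagree with sidecar")
    ev = pd.read_csv(events_p)
    events = [(int(s), str(c)) for s, c in zip(ev["sample"], ev["code"])]
    if events and (min(e[0] for e in events) < 0 or
                   max(e[0] for e in events) >= meta["n_samples"]):
        raise ValueError(f"{events_p}: event index outside recording")
    return EEGRecording(
        data=df.to_numpy().T.astype(float),
        rate_hz=float(meta["rate_hz"]),
        channel_labels=list(meta["channel_labels"]),
        events=events,
    )


def write_waveform(avg: AveragedWaveform, stem) -> None:
    data_p, _, meta_p = _paths(stem)
    data_p.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(avg.data.T, columns=avg.channel_labels).to_csv(
        data_p, index=False, float_format="%.8f"
    )
    meta_p.write_text(
        json.dumps(
            {
                "rate_hz": avg.rate_hz,
                "t0_ms": avg.t0_ms,
                "n_epochs_averaged": avg.n_epochs_averaged,
                "channel_labels": avg.channel_labels,
            }
        )
    )


def read_waveform(stem) -> AveragedWaveform:
    data_p, _, meta_p = _paths(stem)
    meta = json.loads(meta_p.read_text())
    df = pd.read_csv(data_p)
    return AveragedWaveform(
        data=df.to_numpy().T.astype(float),
        rate_hz=float(meta["rate_hz"]),
        channel_labels=list(meta["channel_labels"]),
        t0_ms=float(meta["t0_ms"]),
        n_epochs_averaged=int(meta["n_epochs_averaged"]),
    )


def spectrum_to_csv(spectrum: AmplitudeSpectrum, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"frequency_hz": spectrum.frequencies, "amplitude": spectrum.amplitudes}
    ).to_csv(path, index=False)


def spectrum_from_csv(path, noise_corrected: bool = False) -> AmplitudeSpectrum:
    df = pd.read_csv(path)
    f = df["frequency_hz"].to_numpy()
    if len(f) < 2:
        raise ValueError("spectrum needs at least two bins")
    res = float(f[1] - f[0])
    if not np.allclose(np.diff(f), res, atol=1e-9):
        raise ValueError("non-uniform frequency axis")
    return AmplitudeSpectrum(float(f[0]), res, df["amplitude"].to_numpy(), noise_corrected)
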