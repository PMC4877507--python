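"""Preprocessing chain: filter -> resample -> artifact attenuation ->
common-average reference -> epoch averaging.

All operations preserve channel count, labels and units (microvolts) and
return new :class:`~rhythmtag.simulate.EEGRecording` objects; nothing is
modified in place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import butter, sosfiltfilt, resample_poly

from .simulate import EEGRecording

__all__ = [
    "AveragedWaveform",
    "bandpass",
    "resample",
    "attenuate_artifacts",
    "rereference_common_average",
    "epoch_average",
]

log = logging.getLogger(__name__)


@dataclass
class AveragedWaveform:
    """Trial- or tone-locked average: channel x sample matrix in microvolts.

    ``t0_ms`` is the time of the first retained sample relative to the
    event the epochs were locked to.
    """

    data: np.ndarray
    rate_hz: float
    channel_labels: list
    t0_ms: float
    n_epochs_averaged: int

    @property
    def duration_seconds(self) -> float:
        return self.data.shape[1] / self.rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.data.shape[1]) / self.rate_hz * 1000.0


def bandpass(rec: EEGRecording, high_pass_hz: float, low_pass_hz: float) -> EEGRecording:
    """Zero-phase band limitation: 4th-order Butterworth high-pass and
    low-pass, each applied forward-backward (sosfiltfilt), so phase-locked
    averaging is unaffected.  Removes DC by construction."""
    nyq = rec.rate_hz / 2.0
    if not 0 < high_pass_hz < low_pass_hz < nyq:
        raise ValueError(
            f"need 0 < high_pass ({high_pass_hz}) < low_pass ({low_pass_hz}) "
            f"< Nyquist ({nyq})"
        )
    sos_hp = butter(4, high_pass_hz, btype="highpass", fs=rec.rate_hz, output="sos")
    sos_lp = butter(4, low_pass_hz, btype="lowpass", fs=rec.rate_hz, output="sos")
    out = sosfiltfilt(sos_lp, sosfiltfilt(sos_hp, rec.data, axis=1), axis=1)
    return EEGRecording(out, rec.rate_hz, list(rec.channel_labels), list(rec.events))


def resample(rec: EEGRecording, target_rate_hz: float) -> EEGRecording:
    """Polyphase resampling; event sample indices are remapped by the rate
    ratio with round-half-up."""
    if target_rate_hz > rec.rate_hz:
        raise ValueError("upsampling is not supported (target above original rate)")
    if target_rate_hz == rec.rate_hz:
        return EEGRecording(
            rec.data.copy(), rec.rate_hz, list(rec.channel_labels), list(rec.events)
        )
    frac = Fraction(target_rate_hz / rec.rate_hz).limit_denominator(10000)
    out = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    ratio = target_rate_hz / rec.rate_hz
    events = [(int(np.floor(s * ratio + 0.5)), c) for s, c in rec.events]
    events = [(s, c) for s, c in events if s < out.shape[1]]
    return EEGRecording(out, float(target_rate_hz), list(rec.channel_labels), events)


def attenuate_artifacts(
    rec: EEGRecording, threshold_uv: float, guard_ms: float = 10.0
) -> EEGRecording:
    """Threshold-interpolation artifact attenuator.

    Runs of samples exceeding ``threshold_uv`` in magnitude (expanded by a
    ``guard_ms`` margin on each side) are replaced, per channel, by linear
    interpolation between the surrounding clean samples.  This is a simple
    stand-in for more elaborate artifact-suppression schemes; it removes
    gross burst artifacts while leaving sub-threshold signal untouched.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    guard = round(guard_ms / 1000.0 * rec.rate_hz)
    out = rec.data.copy()
    n = out.shape[1]
    idx = np.arange(n)
    for ch in range(out.shape[0]):
        bad = np.abs(out[ch]) > threshold_uv
        if not bad.any():
            continue
        if guard > 0:
            # dilate the bad mask by the guard on both sides
            kernel = np.ones(2 * guard + 1, dtype=bool)
            bad = np.convolve(bad, kernel, mode="same") > 0
        good = ~bad
        if not good.any():
            out[ch] = 0.0
            continue
        out[ch, bad] = np.interp(idx[bad], idx[good], out[ch, good])
    return EEGRecording(out, rec.rate_hz, list(rec.channel_labels), list(rec.events))


def rereference_common_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs >= 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(out, rec.rate_hz, list(rec.channel_labels), list(rec.events))


def epoch_average(
    rec: EEGRecording,
    trial_onsets,
    start_ms: float,
    end_ms: float,
    baseline_start_ms: float,
    baseline_end_ms: float,
    discard_first_ms: float = 0.0,
) -> AveragedWaveform:
    """Extract epochs relative to each onset, baseline-correct per epoch,
    average, then drop the first ``discard_first_ms``.

    The baseline is the mean over ``[baseline_start_ms, baseline_end_ms)``
    relative to each onset, subtracted per channel per epoch.  The baseline
    window may precede the epoch window (it need only lie within the
    recording).  Onsets whose epoch or baseline window falls outside the
    recording are skipped with a warning; zero usable epochs is an error.
    """
    if end_ms <= start_ms:
        raise ValueError("end_ms must exceed start_ms")
    rate = rec.rate_hz
    i_start = round(start_ms / 1000.0 * rate)
    i_end = round(end_ms / 1000.0 * rate)
    b0 = round(baseline_start_ms / 1000.0 * rate)
    b1 = round(baseline_end_ms / 1000.0 * rate)
    if not b0 < b1:
        raise ValueError("baseline window must be nonempty")
    n_len = i_end - i_start
    acc = np.zeros((rec.n_channels, n_len))
    n_used = 0
    for onset in np.asarray(trial_onsets, dtype=int):
        lo, hi = onset + i_start, onset + i_end
        if lo < 0 or hi > rec.n_samples or onset + b0 < 0 or onset + b1 > rec.n_samples:
            log.warning("skipping onset at sample %d: epoch outside recording", onset)
            continue
        epoch = rec.data[:, lo:hi]
        base = rec.data[:, onset + b0 : onset + b1].mean(axis=1, keepdims=True)
        acc += epoch - base
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable epochs")
    avg = acc / n_used
    n_drop = round(discard_first_ms / 1000.0 * rate)
    avg = avg[:, n_drop:]
    return AveragedWaveform(
        data=avg,
        rate_hz=rate,
        channel_labels=list(rec.channel_labels),
        t0_ms=start_ms + discard_first_ms,
        n_epochs_averaged=n_used,
    )
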