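"""Transient evoked-response (ERP) analysis.

Epochs locked to selected tone onsets are averaged per channel with a
pre-stimulus baseline; waveforms are pooled over small frontal electrode
groups per hemisphere; the grand-average peak latency fixes a +/-50 ms
window in which each subject's response magnitude is measured as the
signed trapezoidal area under the curve (uV*ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AveragedWaveform, epoch_average
from .simulate import EEGRecording
from .stimulus import RhythmPattern

__all__ = [
    "ErpResult",
    "erp_epoch_average",
    "channel_group_mean",
    "grand_peak_latency",
    "area_under_curve",
    "select_tone_onsets",
]


@dataclass
class ErpResult:
    subject_id: str
    auc_left: float  # uV*ms
    auc_right: float
    peak_latency_ms: dict  # group name -> latency used


def select_tone_onsets(
    trial_starts,
    pattern: RhythmPattern,
    rate_hz: float,
    repetitions: int,
    rule: str = "sequence_start",
) -> np.ndarray:
    """Tone onsets to epoch on, derived from trial starts and the rhythm.

    ``sequence_start``: the first tone of every pattern cycle.
    ``after_silence``: every tone whose preceding slot (cyclically) is
    silent — for patterns starting with a tone run, both rules include the
    cycle-initial tone; ``after_silence`` may add more.
    """
    flags = pattern.onset_flags
    n = pattern.n_slots
    if rule == "sequence_start":
        slots = [next(i for i, f in enumerate(flags) if f)]
    elif rule == "after_silence":
        slots = [i for i, f in enumerate(flags) if f and not flags[(i - 1) % n]]
    else:
        raise ValueError(f"unknown onset rule {rule!r}")
    onsets = []
    for start in np.asarray(trial_starts, dtype=int):
        for rep in range(repetitions):
            for slot in slots:
                t = (rep * n + slot) * pattern.ioi_seconds
                onsets.append(start + round(t * rate_hz))
    return np.array(sorted(onsets), dtype=int)


def erp_epoch_average(
    rec: EEGRecording,
    tone_onsets,
    start_ms: float = -100.0,
    end_ms: float = 300.0,
    baseline=(-100.0, 0.0),
) -> AveragedWaveform:
    """Average tone-locked epochs with a pre-stimulus baseline."""
    return epoch_average(
        rec,
        tone_onsets,
        start_ms=start_ms,
        end_ms=end_ms,
        baseline_start_ms=baseline[0],
        baseline_end_ms=baseline[1],
        discard_first_ms=0.0,
    )


def channel_group_mean(avg: AveragedWaveform, channel_subset) -> np.ndarray:
    """Mean waveform over a named channel subset."""
    subset = list(channel_subset)
    if not subset:
        raise ValueError("empty channel subset")
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate label in channel subset")
    try:
        rows = [avg.channel_labels.index(lbl) for lbl in subset]
    except ValueError as e:
        raise ValueError(f"unknown channel label: {e}") from None
    return avg.data[rows].mean(axis=0)


def grand_peak_latency(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    search_window_ms=(50.0, 300.0),
) -> float:
    """Latency (ms) of the largest-magnitude point in the search window;
    ties resolve to the earliest sample."""
    lo, hi = search_window_ms
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError("empty search window")
    seg = np.abs(waveform[mask])
    return float(times_ms[mask][int(np.argmax(seg))])  # argmax takes first max


def area_under_curve(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    center_ms: float,
    half_width_ms: float = 50.0,
) -> float:
    """Signed trapezoidal integral (uV*ms) over ``center +/- half_width``."""
    lo, hi = center_ms - half_width_ms, center_ms + half_width_ms
    if lo < times_ms[0] - 1e-9 or hi > times_ms[-1] + 1e-9:
        raise ValueError("integration window clipped by epoch edge")
    mask = (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)
    return float(np.trapezoid(waveform[mask], times_ms[mask]))
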