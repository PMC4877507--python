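"""Synthetic multi-channel EEG with known ground truth.

The generator emulates an infant frequency-tagging session: a subject
passively hears back-to-back trials of a cyclic rhythm while EEG is
recorded.  Each recording is the sum of

* steady-state components — pure sinusoids at the tagged frequencies,
  phase-locked to each trial onset, with a smooth zero-mean scalp
  topography whose mean absolute gain is 1 (so the channel-averaged
  spectral amplitude equals the ground-truth amplitude, and common-average
  re-referencing leaves the component untouched);
* an event-related transient — a raised-cosine positive bump after every
  tone onset (default peak 175 ms), with a front-positive/back-negative
  dipolar topography;
* 1/f ("pink") background noise, independent per channel;
* optional high-amplitude burst artifacts.

Amplitudes are in microvolts throughout.  Everything is driven by a master
seed through ``numpy.random.SeedSequence`` so a cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stimulus import EXP1_ONSETS, RhythmPattern, build_pattern

__all__ = [
    "EEGRecording",
    "SubjectGroundTruth",
    "SubjectMeta",
    "CohortConfig",
    "pink_noise",
    "simulate_subject",
    "simulate_cohort",
    "default_channel_labels",
    "frontal_channel_groups",
]

TRIAL_START = "trial_start"
TONE_ONSET = "tone_onset"


@dataclass
class EEGRecording:
    """Channel x sample matrix (microvolts) with event markers."""

    data: np.ndarray  # (n_channels, n_samples)
    rate_hz: float
    channel_labels: list
    events: list  # of (sample_index, code) tuples

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def event_samples(self, code: str) -> np.ndarray:
        return np.array([s for s, c in self.events if c == code], dtype=int)


@dataclass
class SubjectGroundTruth:
    ssep_amp_uv: dict  # frequency (Hz) -> true phase-locked amplitude
    erp_peak_latency_ms: float
    erp_amp_uv: float
    noise_level_uv: float


@dataclass
class SubjectMeta:
    subject_id: str
    group: str
    music_classes: bool
    parent_training_years: float
    listening_hours: float
    age_months: float


@dataclass
class CohortConfig:
    """Study-design knobs for a simulated cohort.

    Defaults mirror the first infant experiment: a 6-slot rhythm at 333 ms
    IOI, 17 cycles per 34 s trial, 32 trials, and group sizes 13 (music
    classes) vs 46 (none).  Channel count defaults to 32 for tractability;
    the recording montage of the emulated system had 124.
    """

    n_subjects: dict = field(default_factory=lambda: {"music": 13, "no_music": 46})
    ssep_mean_uv: dict = field(
        default_factory=lambda: {1.0: 0.25, 1.5: 0.25, 2.0: 0.15, 2.5: 0.15, 3.0: 0.35}
    )
    ssep_sd_uv: dict = field(default_factory=dict)  # default: 30% of mean
    ssep_sd_frac: float = 0.3
    erp_amp_uv: float = 5.0
    erp_amp_sd_uv: float = 1.5
    erp_latency_ms: float = 175.0
    erp_width_ms: float = 150.0
    noise_level_uv: float = 15.0
    noise_exponent: float = 1.0
    artifact_rate_hz: float = 0.0  # bursts per second per channel
    artifact_amp_uv: float = 500.0
    n_channels: int = 32
    rate_hz: float = 1000.0
    n_trials: int = 32
    repetitions_per_trial: int = 17
    onset_flags: tuple = EXP1_ONSETS
    ioi_seconds: float = 1.0 / 3.0
    lead_in_seconds: float = 2.0
    tail_seconds: float = 1.0
    scenario: str = "exp1"  # exp1: boost duple only; exp2: scale all
    boost_factor: float = 1.0
    boosted_group: str = "music"
    duple_hz: float = 1.5
    seed: int = 0

    def pattern(self) -> RhythmPattern:
        return build_pattern(self.onset_flags, self.ioi_seconds, 990.0, 0.010)

    @property
    def trial_seconds(self) -> float:
        return self.repetitions_per_trial * self.pattern().duration_seconds


def default_channel_labels(n_channels: int) -> list:
    """Labels for a schematic montage: rows run front to back, each row has
    a left (L) and right (R) electrode.  Row 1 is frontal-most."""
    labels = []
    for i in range(n_channels):
        side = "L" if i % 2 == 0 else "R"
        labels.append(f"{side}{i // 2 + 1}")
    return labels


def frontal_channel_groups(n_channels: int, per_side: int = 8):
    """Default ERP electrode groups: the ``per_side`` frontal-most left and
    right channels of the schematic montage."""
    labels = default_channel_labels(n_channels)
    left = [l for l in labels if l.startswith("L")][:per_side]
    right = [l for l in labels if l.startswith("R")][:per_side]
    return left, right


def pink_noise(n_samples: int, exponent: float, rate_hz: float, rng) -> np.ndarray:
    """Zero-mean noise with power spectral density proportional to 1/f^exponent.

    Generated by shaping white Gaussian noise in the frequency domain and
    normalising to unit RMS.  ``rng`` is a ``numpy.random.Generator`` or an
    integer seed.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n_samples)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _component_topography(n_channels: int, phase: float) -> np.ndarray:
    """Smooth zero-mean gain profile with mean |gain| = 1 across channels."""
    g = np.cos(2 * np.pi * np.arange(n_channels) / n_channels + phase)
    g -= g.mean()
    return g / np.abs(g).mean()


def _erp_topography(n_channels: int) -> np.ndarray:
    """Dipolar front-positive profile, zero-mean, frontal gain ~1.

    Channels are ordered front to back in L/R pairs, so the gradient runs
    over the row index."""
    rows = np.arange(n_channels) // 2
    g = np.cos(np.pi * rows / max(rows.max(), 1))
    g = g - g.mean()
    return g / g.max()


def tone_onset_samples(
    trial_start: int, pattern: RhythmPattern, rate_hz: float, repetitions: int
) -> np.ndarray:
    """Sample indices of every tone onset within one trial."""
    onsets = []
    for rep in range(repetitions):
        for slot, flag in enumerate(pattern.onset_flags):
            if flag:
                t = (rep * pattern.n_slots + slot) * pattern.ioi_seconds
                onsets.append(trial_start + round(t * rate_hz))
    return np.array(onsets, dtype=int)


def simulate_subject(config: CohortConfig, meta: SubjectMeta, seed):
    """Simulate one subject's recording plus its ground truth.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)
    pattern = config.pattern()
    rate = config.rate_hz
    trial_len = round(config.trial_seconds * rate)
    lead = round(config.lead_in_seconds * rate)
    n_samples = lead + config.n_trials * trial_len + round(config.tail_seconds * rate)
    n_ch = config.n_channels

    # Per-subject true amplitudes drawn from the group distribution.
    means = dict(config.ssep_mean_uv)
    if config.scenario == "exp1" and meta.group == config.boosted_group:
        means[config.duple_hz] = means.get(config.duple_hz, 0.0) * config.boost_factor
    elif config.scenario == "exp2" and meta.group == config.boosted_group:
        means = {f: a * config.boost_factor for f, a in means.items()}
    true_amp = {}
    for f, m in means.items():
        sd = config.ssep_sd_uv.get(f, config.ssep_sd_frac * m)
        true_amp[f] = float(max(0.0, rng.normal(m, sd)))
    erp_amp = float(max(0.0, rng.normal(config.erp_amp_uv, config.erp_amp_sd_uv)))

    data = np.zeros((n_ch, n_samples))
    events = []

    # Steady-state components, phase-locked to each trial onset.
    topo = {
        f: _component_topography(n_ch, phase=2 * np.pi * k / max(len(true_amp), 1))
        for k, f in enumerate(sorted(true_amp))
    }
    t_trial = np.arange(trial_len) / rate
    trial_starts = [lead + i * trial_len for i in range(config.n_trials)]
    ssep_block = np.zeros((n_ch, trial_len))
    for f, a in true_amp.items():
        # per-subject component phase, constant across trials (phase-locked
        # to trial onset); randomising it avoids systematic interference
        # with the tone-transient harmonics at shared bins
        phi = rng.uniform(0, 2 * np.pi)
        ssep_block += a * np.outer(topo[f], np.cos(2 * np.pi * f * t_trial + phi))

    # ERP transient: raised-cosine bump after every tone onset.
    bump_len = round(config.erp_width_ms / 1000.0 * rate)
    tb = np.arange(bump_len) / rate * 1000.0  # ms
    center = config.erp_width_ms / 2.0
    bump = 0.5 * (1 + np.cos(2 * np.pi * (tb - center) / config.erp_width_ms))
    bump_start_ms = config.erp_latency_ms - center
    etopo = _erp_topography(n_ch)
    erp_block = np.zeros((n_ch, trial_len + bump_len))
    rel_onsets = tone_onset_samples(0, pattern, rate, config.repetitions_per_trial)
    for o in rel_onsets:
        i0 = o + round(bump_start_ms / 1000.0 * rate)
        erp_block[:, i0 : i0 + bump_len] += erp_amp * np.outer(etopo, bump)

    for start in trial_starts:
        events.append((start, TRIAL_START))
        data[:, start : start + trial_len] += ssep_block
        stop = min(start + trial_len + bump_len, n_samples)
        data[:, start:stop] += erp_block[:, : stop - start]
        for o in tone_onset_samples(start, pattern, rate, config.repetitions_per_trial):
            events.append((int(o), TONE_ONSET))

    # Background noise.
    if config.noise_level_uv > 0:
        for ch in range(n_ch):
            data[ch] += config.noise_level_uv * pink_noise(
                n_samples, config.noise_exponent, rate, rng
            )

    # Burst artifacts: Hann-windowed high-amplitude segments.
    if config.artifact_rate_hz > 0:
        dur_s = n_samples / rate
        for ch in range(n_ch):
            n_bursts = rng.poisson(config.artifact_rate_hz * dur_s)
            for _ in range(n_bursts):
                blen = round(rng.uniform(0.1, 0.3) * rate)
                b0 = rng.integers(0, max(n_samples - blen, 1))
                amp = config.artifact_amp_uv * rng.uniform(1.0, 2.0)
                sign = rng.choice([-1.0, 1.0])
                data[ch, b0 : b0 + blen] += sign * amp * np.hanning(blen)

    rec = EEGRecording(
        data=data,
        rate_hz=rate,
        channel_labels=default_channel_labels(n_ch),
        events=sorted(events),
    )
    truth = SubjectGroundTruth(
        ssep_amp_uv=true_amp,
        erp_peak_latency_ms=config.erp_latency_ms,
        erp_amp_uv=erp_amp,
        noise_level_uv=config.noise_level_uv,
    )
    return rec, truth


def cohort_metas(config: CohortConfig, rng=None) -> list:
    """Subject metadata rows for every group in the cohort config."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    metas = []
    i = 0
    for group, n in config.n_subjects.items():
        if n < 2:
            raise ValueError(f"group {group!r} needs >= 2 subjects for statistics")
        for _ in range(n):
            trained = group in ("music", "trained")
            years = (
                float(rng.uniform(5, 15)) if trained else float(rng.uniform(0, 4.5))
            )
            metas.append(
                SubjectMeta(
                    subject_id=f"S{i:03d}",
                    group=group,
                    music_classes=trained,
                    parent_training_years=round(years, 1),
                    listening_hours=round(float(rng.lognormal(1.5, 0.6)), 1),
                    age_months=round(
                        float(rng.normal(7.3 if config.scenario == "exp1" else 15.5, 0.4)), 1
                    ),
                )
            )
            i += 1
    return metas


def simulate_cohort(config: CohortConfig):
    """Simulate every subject in the cohort.

    Returns ``(subjects, table)`` where ``subjects`` is a list of
    ``(meta, recording, truth)`` and ``table`` is the cohort metadata as a
    DataFrame.  Per-subject seeds are spawned deterministically from
    ``config.seed``.
    """
    master = np.random.SeedSequence(config.seed)
    meta_seed, *subject_seeds = master.spawn(1 + sum(config.n_subjects.values()))
    metas = cohort_metas(config, np.random.default_rng(meta_seed))
    subjects = []
    for meta, sseed in zip(metas, subject_seeds):
        rec, truth = simulate_subject(config, meta, sseed)
        subjects.append((meta, rec, truth))
    table = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "music_classes": m.music_classes,
                "parent_training_years": m.parent_training_years,
                "listening_hours": m.listening_hours,
                "age_months": m.age_months,
                **{f"true_amp_{f}": a for f, a in t.ssep_amp_uv.items()},
                "true_erp_amp": t.erp_amp_uv,
            }
            for (m, _, t) in subjects
        ]
    )
    return subjects, table


def iter_cohort(config: CohortConfig):
    """Generator variant of :func:`simulate_cohort` (one subject in memory
    at a time); yields ``(meta, recording, truth)``."""
    master = np.random.SeedSequence(config.seed)
    meta_seed, *subject_seeds = master.spawn(1 + sum(config.n_subjects.values()))
    metas = cohort_metas(config, np.random.default_rng(meta_seed))
    for meta, sseed in zip(metas, subject_seeds):
        rec, truth = simulate_subject(config, meta, sseed)
        yield meta, rec, truth
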