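"""Rhythmic stimulus construction and envelope spectra.

A rhythm is a cyclic sequence of isochronous slots, each either carrying a
pure tone or silent.  The slot rate defines the *beat* frequency (1/IOI);
grouping beats by an integer defines *meter* frequencies (beat/2 = duple,
beat/3 = triple, beat/4 = quadruple).  The amplitude envelope of the
synthesized audio, Fourier-transformed over a whole number of pattern
cycles, shows energy only at harmonics of the pattern repetition rate; the
subset of those harmonics that carry appreciable energy are the frequencies
the EEG analysis is tagged to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import hilbert, resample as sp_resample

__all__ = [
    "RhythmPattern",
    "AudioSignal",
    "AmplitudeSpectrum",
    "FrequencySet",
    "build_pattern",
    "synthesize",
    "hilbert_envelope",
    "amplitude_spectrum",
    "metric_frequency",
    "frequencies_of_interest",
    "write_wav",
    "EXP1_ONSETS",
    "EXP2_ONSETS",
]

# Six-slot pattern: tone-silence-tone-tone-tone-silence.
EXP1_ONSETS = (1, 0, 1, 1, 1, 0)

# Twelve-slot pattern: a run of tones followed by rests, with tones on all
# strong beats of a four-beat grouping and the cycle-initial tone preceded
# by a silence.  Its envelope carries energy at every 0.25 Hz harmonic from
# 0.75 to 3 Hz.  The published figure for this stimulus is not reproduced
# in the extracted text, so this is a documented plausible default; any
# slot sequence can be passed instead.
EXP2_ONSETS = (1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 0, 0)


@dataclass(frozen=True)
class RhythmPattern:
    """Slot-level rhythm: binary onset flags on an isochronous grid."""

    onset_flags: tuple
    ioi_seconds: float
    carrier_hz: float
    ramp_seconds: float

    @property
    def n_slots(self) -> int:
        return len(self.onset_flags)

    @property
    def duration_seconds(self) -> float:
        """One cycle of the pattern."""
        return self.n_slots * self.ioi_seconds

    @property
    def repetition_hz(self) -> float:
        """Pattern repetition frequency (cycle rate)."""
        return 1.0 / self.duration_seconds

    @property
    def beat_hz(self) -> float:
        return 1.0 / self.ioi_seconds


@dataclass
class AudioSignal:
    samples: np.ndarray
    rate_hz: float

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass
class AmplitudeSpectrum:
    """Uniformly spaced single-sided amplitude spectrum.

    ``amplitudes[k]`` sits at frequency ``start_hz + k * resolution_hz``.
    After neighbour-bin noise subtraction (``noise_corrected=True``) values
    may be negative, and bins too close to the spectrum edge to have a full
    neighbour set are NaN (invalid, never silently zeroed).
    """

    start_hz: float
    resolution_hz: float
    amplitudes: np.ndarray
    noise_corrected: bool = False

    @property
    def frequencies(self) -> np.ndarray:
        return self.start_hz + np.arange(len(self.amplitudes)) * self.resolution_hz

    def nearest_bin(self, target_hz: float) -> int:
        """Index of the bin closest to ``target_hz``; exact midpoints break
        toward the lower frequency."""
        x = (target_hz - self.start_hz) / self.resolution_hz
        idx = int(math.ceil(x - 0.5))  # round half down
        if idx < 0 or idx >= len(self.amplitudes):
            raise ValueError(f"{target_hz} Hz outside spectrum range")
        return idx


@dataclass
class FrequencySet:
    """Tagged analysis frequencies derived from a stimulus spectrum."""

    beat_hz: float
    meter_hz: dict = field(default_factory=dict)
    stimulus_present_hz: list = field(default_factory=list)
    stimulus_absent_hz: list = field(default_factory=list)


_METER_NAMES = {2: "duple", 3: "triple", 4: "quadruple"}


def build_pattern(onset_flags, ioi_seconds, carrier_hz, ramp_seconds) -> RhythmPattern:
    """Validate and construct a :class:`RhythmPattern`."""
    flags = tuple(int(f) for f in onset_flags)
    if len(flags) == 0:
        raise ValueError("onset_flags must be nonempty")
    if any(f not in (0, 1) for f in flags):
        raise ValueError("onset_flags must be binary (0/1)")
    if ioi_seconds <= 0 or carrier_hz <= 0:
        raise ValueError("ioi_seconds and carrier_hz must be positive")
    if ramp_seconds < 0:
        raise ValueError("ramp_seconds must be nonnegative")
    if 2 * ramp_seconds > ioi_seconds:
        raise ValueError(
            f"rise+fall ramps (2 x {ramp_seconds} s) do not fit in one "
            f"{ioi_seconds} s slot"
        )
    return RhythmPattern(flags, float(ioi_seconds), float(carrier_hz), float(ramp_seconds))


def synthesize(
    pattern: RhythmPattern,
    rate_hz: float,
    repetitions: int,
    phase_mode: str = "continuous",
) -> AudioSignal:
    """Render ``repetitions`` cycles of the pattern as audio.

    Every tone slot carries a unit-amplitude carrier sinusoid with linear
    rise/fall ramps at the slot edges (each tone is ramped individually, so
    consecutive tones are separated by a brief envelope dip — this is what
    puts acoustic energy at the beat frequency itself).  ``phase_mode``
    controls only the carrier phase: ``continuous`` keeps a global running
    phase, ``reset`` restarts the carrier at zero phase at each tone onset.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if phase_mode not in ("continuous", "reset"):
        raise ValueError(f"unknown phase_mode {phase_mode!r}")
    if rate_hz < 4 * pattern.carrier_hz:
        raise ValueError(
            f"rate {rate_hz} Hz too low for {pattern.carrier_hz} Hz carrier "
            "(need >= 4x)"
        )
    n_total = round(repetitions * pattern.n_slots * pattern.ioi_seconds * rate_hz)
    out = np.zeros(n_total)
    t = np.arange(n_total) / rate_hz
    n_ramp = round(pattern.ramp_seconds * rate_hz)
    for rep in range(repetitions):
        for slot, flag in enumerate(pattern.onset_flags):
            if not flag:
                continue
            k = rep * pattern.n_slots + slot
            i0 = round(k * pattern.ioi_seconds * rate_hz)
            i1 = round((k + 1) * pattern.ioi_seconds * rate_hz)
            seg_t = t[i0:i1]
            if phase_mode == "continuous":
                carrier = np.sin(2 * np.pi * pattern.carrier_hz * seg_t)
            else:
                carrier = np.sin(2 * np.pi * pattern.carrier_hz * (seg_t - seg_t[0]))
            env = np.ones(i1 - i0)
            if n_ramp > 0:
                ramp = np.arange(1, n_ramp + 1) / n_ramp
                env[:n_ramp] = ramp
                env[-n_ramp:] = np.minimum(env[-n_ramp:], ramp[::-1])
            out[i0:i1] = env * carrier
    return AudioSignal(out, float(rate_hz))


def hilbert_envelope(signal: AudioSignal) -> AudioSignal:
    """Instantaneous amplitude: magnitude of the analytic signal."""
    if len(signal.samples) == 0:
        raise ValueError("empty signal")
    return AudioSignal(np.abs(hilbert(signal.samples)), signal.rate_hz)


def amplitude_spectrum(signal: AudioSignal) -> AmplitudeSpectrum:
    """Single-sided DFT amplitude spectrum, calibrated so a sinusoid of
    amplitude A at an exact bin frequency reads A; resolution = 1/duration."""
    x = np.asarray(signal.samples, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty signal")
    spec = np.abs(np.fft.rfft(x)) / n
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0  # Nyquist bin is not doubled
    return AmplitudeSpectrum(0.0, signal.rate_hz / n, spec, noise_corrected=False)


def decimate_envelope(env: AudioSignal, target_rate_hz: float) -> AudioSignal:
    """Resample an envelope to a lower rate so stimulus and EEG spectra
    share a bin grid.

    Uses Fourier resampling: for the whole-cycle windows used here the
    signal is circularly periodic, so spectrum truncation is exact and
    introduces no edge transients (a time-domain decimation filter would).
    """
    n_out = round(len(env.samples) * target_rate_hz / env.rate_hz)
    y = sp_resample(env.samples, n_out)
    return AudioSignal(y, target_rate_hz)


def metric_frequency(beat_hz: float, grouping: int) -> float:
    """Meter frequency for beats grouped by ``grouping`` (2=duple, ...)."""
    if grouping < 1 or int(grouping) != grouping:
        raise ValueError("grouping must be a positive integer")
    return beat_hz / grouping


def frequencies_of_interest(
    stim_spectrum: AmplitudeSpectrum,
    band_hz,
    exclude_hz=(),
    energy_threshold: float = 0.05,
    groupings=(2, 3),
) -> FrequencySet:
    """Derive tagged frequencies from a stimulus envelope spectrum.

    Bins inside ``band_hz`` whose amplitude exceeds ``energy_threshold``
    times the in-band maximum, minus ``exclude_hz``, are the
    stimulus-present frequencies.  The control (stimulus-absent) grid sits
    halfway between the harmonic grid points: each present frequency minus
    half the harmonic spacing (the spacing is the GCD of the present-set
    differences, i.e. the pattern repetition frequency).
    """
    if stim_spectrum.noise_corrected:
        raise ValueError("frequencies_of_interest expects an uncorrected spectrum")
    lo, hi = band_hz
    if not lo < hi:
        raise ValueError("empty band")
    freqs = stim_spectrum.frequencies
    amps = stim_spectrum.amplitudes
    in_band = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not in_band.any():
        raise ValueError("band outside spectrum range")
    band_amps = amps[in_band]
    band_freqs = freqs[in_band]
    if band_amps.max() <= 0:
        return FrequencySet(beat_hz=float("nan"))
    keep = band_amps > energy_threshold * band_amps.max()
    present = [float(round(f, 9)) for f in band_freqs[keep]]
    present = [
        f for f in present if not any(abs(f - e) < 1e-6 for e in exclude_hz)
    ]
    if not present:
        return FrequencySet(beat_hz=float("nan"))
    present = sorted(present)
    if len(present) > 1:
        diffs = np.diff(present)
        spacing = diffs[0]
        for d in diffs[1:]:  # GCD of spacings, robust to missing harmonics
            spacing = math.gcd(round(spacing * 1e6), round(d * 1e6)) / 1e6
    else:
        spacing = present[0]
    absent = sorted(round(f - spacing / 2, 9) for f in present)
    beat = present[-1]
    meters = {
        _METER_NAMES[g]: metric_frequency(beat, g)
        for g in groupings
        if any(abs(metric_frequency(beat, g) - f) < 1e-6 for f in present)
    }
    return FrequencySet(
        beat_hz=beat,
        meter_hz=meters,
        stimulus_present_hz=present,
        stimulus_absent_hz=absent,
    )


def write_wav(signal: AudioSignal, path, peak: float = 0.9) -> None:
    """Write audio as 16-bit PCM WAV, scaled to ``peak`` of full scale."""
    x = np.asarray(signal.samples, dtype=float)
    m = np.abs(x).max()
    if m > 0:
        x = x / m * peak
    wavfile.write(str(path), int(signal.rate_hz), (x * 32767).astype(np.int16))
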