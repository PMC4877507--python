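"""Steady-state evoked-potential extraction.

Per channel, the trial-averaged waveform is Fourier-transformed; the
residual background is estimated per frequency bin as the mean amplitude
at the bins 3-5 steps away on both sides and subtracted; corrected spectra
are averaged over all channels (avoiding electrode selection bias); the
response at each tagged frequency is the maximum within a 3-bin band
centred on it.  Corrected amplitudes may be negative — they are kept
signed so that the null distribution stays centred on zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import AveragedWaveform
from .stimulus import AmplitudeSpectrum, amplitude_spectrum, AudioSignal

__all__ = [
    "SubjectResult",
    "spectrum_per_channel",
    "subtract_noise",
    "average_across_channels",
    "peak_amplitude",
    "noise_floor",
    "zscore_exclude",
]


@dataclass
class SubjectResult:
    """Channel-averaged, noise-subtracted amplitudes for one subject."""

    subject_id: str
    amp_by_freq: dict  # frequency (Hz) -> amplitude (uV)
    noise_floor_uv: float
    included: bool = True
    extras: dict = field(default_factory=dict)


def spectrum_per_channel(avg: AveragedWaveform) -> list:
    """One uncorrected amplitude spectrum per channel; resolution is the
    reciprocal of the averaged-epoch duration."""
    if avg.duration_seconds < 4.0:
        raise ValueError("averaged waveform shorter than 4 s; spectrum too coarse")
    return [
        amplitude_spectrum(AudioSignal(avg.data[ch], avg.rate_hz))
        for ch in range(avg.data.shape[0])
    ]


def subtract_noise(
    spectrum: AmplitudeSpectrum, offset_bins_low: int = 3, offset_bins_high: int = 5
) -> AmplitudeSpectrum:
    """Neighbour-bin noise-floor subtraction.

    Each bin has the mean of the bins at offsets +/-(low..high) (default
    -5..-3 and +3..+5, six bins) subtracted.  Bins closer than
    ``offset_bins_high`` to either edge have no full neighbour set and are
    marked invalid (NaN).
    """
    if spectrum.noise_corrected:
        raise ValueError("spectrum is already noise-corrected")
    if not 0 < offset_bins_low <= offset_bins_high:
        raise ValueError("need 0 < offset_bins_low <= offset_bins_high")
    a = np.asarray(spectrum.amplitudes, dtype=float)
    n = len(a)
    offsets = list(range(-offset_bins_high, -offset_bins_low + 1)) + list(
        range(offset_bins_low, offset_bins_high + 1)
    )
    out = np.full(n, np.nan)
    lo, hi = offset_bins_high, n - offset_bins_high
    if hi > lo:
        neigh = np.mean([a[lo + off : hi + off] for off in offsets], axis=0)
        out[lo:hi] = a[lo:hi] - neigh
    return AmplitudeSpectrum(
        spectrum.start_hz, spectrum.resolution_hz, out, noise_corrected=True
    )


def average_across_channels(spectra) -> AmplitudeSpectrum:
    """Bin-wise mean over per-channel spectra (identical grids required)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if (
            s.start_hz != ref.start_hz
            or abs(s.resolution_hz - ref.resolution_hz) > 1e-12
            or len(s.amplitudes) != len(ref.amplitudes)
        ):
            raise ValueError("spectra have mismatched bin grids")
        if s.noise_corrected != ref.noise_corrected:
            raise ValueError("cannot mix corrected and uncorrected spectra")
    stack = np.vstack([s.amplitudes for s in spectra])
    return AmplitudeSpectrum(
        ref.start_hz, ref.resolution_hz, stack.mean(axis=0), ref.noise_corrected
    )


def peak_amplitude(
    spectrum: AmplitudeSpectrum, target_hz: float, band_bins: int = 3
) -> float:
    """Maximum amplitude within a ``band_bins``-wide band centred on the bin
    nearest ``target_hz`` (exact midpoints resolve to the lower bin)."""
    if band_bins < 1 or band_bins % 2 == 0:
        raise ValueError("band_bins must be a positive odd integer")
    k = spectrum.nearest_bin(target_hz)
    half = band_bins // 2
    lo, hi = k - half, k + half + 1
    if lo < 0 or hi > len(spectrum.amplitudes):
        raise ValueError(f"{band_bins}-bin band around {target_hz} Hz leaves spectrum")
    band = spectrum.amplitudes[lo:hi]
    if np.isnan(band).any():
        raise ValueError(
            f"band around {target_hz} Hz touches invalid (edge) bins"
        )
    return float(np.max(band))


def noise_floor(spectrum: AmplitudeSpectrum, absent_freqs) -> float:
    """Mean peak amplitude over the stimulus-absent control frequencies."""
    absent_freqs = list(absent_freqs)
    if not absent_freqs:
        raise ValueError("empty control frequency list")
    return float(np.mean([peak_amplitude(spectrum, f) for f in absent_freqs]))


def zscore_exclude(values, cutoff: float = 3.0) -> np.ndarray:
    """Inclusion mask from a z-score outlier rule across subjects.

    ``values`` are per-subject summary amplitudes (mean over the tagged
    frequencies).  z uses the sample SD (ddof=1); if the SD is zero all
    subjects are included.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("z-score exclusion needs >= 3 subjects")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(len(x), dtype=bool)
    z = (x - x.mean()) / sd
    return np.abs(z) <= cutoff
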