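# Methods

`rhythmtag` implements an EEG frequency-tagging analysis of neural
entrainment to auditory rhythm, together with a synthetic-EEG test bench
that makes every stage verifiable against known ground truth.

## Stimuli

A rhythm is a cyclic sequence of isochronous *slots* (inter-onset interval
`ioi_seconds`, default exactly 1/3 s = 180 bpm), each slot either carrying
a 990 Hz pure tone or silent. Two reference patterns ship with the package:

* a 6-slot pattern `tone-silence-tone-tone-tone-silence` (2 s cycle,
  repetition rate 0.5 Hz), metrically ambiguous between duple and triple
  grouping;
* a 12-slot pattern `(1,1,1,1,1,1,1,0,1,0,0,0)` (4 s cycle, 0.25 Hz) with
  quadruple-meter salience. The original figure specifying this
  arrangement is not available in the extracted source material, so this
  is a documented plausible default chosen so that its envelope carries
  energy at every 0.25 Hz harmonic from 0.75 to 3 Hz; any slot sequence
  can be supplied instead.

Each tone occupies its full slot with 10 ms linear rise/fall ramps applied
*per tone*, so consecutive tones are separated by a brief envelope dip.
This detail matters: with full-slot tones and no per-tone ramps, a boxcar
spanning exactly one beat period contributes nothing at the beat frequency
(3 Hz); the ramp dips are what put acoustic energy there. The carrier
phase is continuous across slots by default (`reset` mode restarts each
tone at zero phase); the envelope, and hence the tagged frequencies, is
essentially unaffected by this choice.

The amplitude envelope is the magnitude of the analytic (Hilbert) signal.
It is resampled to 200 Hz by Fourier resampling — exact for the
whole-cycle windows used here, since the signal is circularly periodic —
so that stimulus and EEG spectra share one bin grid. The single-sided DFT
amplitude spectrum is calibrated so a sinusoid of amplitude A at an exact
bin frequency reads A; resolution is the reciprocal of the window length.

Stimulus-present frequencies are the bins within 0.5–3 Hz whose amplitude
exceeds 5 % of the in-band maximum, minus 0.5 Hz itself (removed because
the EEG high-pass sits there). The control (stimulus-absent) grid places
one frequency halfway below each present harmonic (present minus half the
harmonic spacing). For the 6-slot rhythm this derives
{1, 1.5, 2, 2.5, 3} / {0.75, 1.25, 1.75, 2.25, 2.75} Hz, and for the
12-slot rhythm {0.75 … 3} / {0.625 … 2.875} Hz in 0.25 Hz steps. Meter
labels (duple/triple/quadruple) attach to beat/2, beat/3, beat/4 when
present; the groupings considered are a preset parameter ((2,3) for the
ambiguous rhythm, (2,4) for the quadruple one) because metrical relevance
is perceptual, not deducible from slot-count divisibility.

## Synthetic EEG

Each simulated subject is a channels × samples matrix (µV) containing:

* **Steady-state components** — one sinusoid per tagged frequency,
  phase-locked to each trial onset with a per-subject random phase,
  amplitude drawn per subject from the group distribution (truncated
  normal, SD defaulting to 30 % of the mean). The scalp topography of each
  component is a smooth cosine profile across channels, constructed
  zero-mean with mean absolute gain 1: zero-mean means common-average
  re-referencing leaves the component untouched, and unit mean |gain|
  makes the channel-averaged spectral amplitude equal the ground-truth
  amplitude exactly.
* **A tone transient** — a raised-cosine positive bump (150 ms wide,
  peaking 175 ms after every tone onset by default) with a dipolar
  front-positive/back-negative topography. Because the transient recurs
  with the rhythm, its harmonics land on the same tagged bins as the
  steady-state components; this is physiologically faithful but means
  validation scenarios that need a clean steady-state ground truth set the
  transient amplitude to zero (recovery tests) or small (group-effect
  power scenarios).
* **1/f background noise** per channel, generated by spectral shaping of
  white Gaussian noise (PSD ∝ 1/f^exponent, default exponent 1), scaled to
  a configurable RMS (default 15 µV).
* **Optional burst artifacts** — Hann-windowed segments of 0.1–0.3 s at
  hundreds of µV, Poisson-placed per channel, to exercise the artifact
  attenuator. They model gross movement artifacts only.

The montage is schematic: channels in front-to-back rows of left/right
pairs (default 32 channels; the emulated recording system had 124). There
is no forward head model, no channel covariance structure beyond the
smooth topographies, no eye-blink/cardiac artifact taxonomy, and the ERP
is a single positive component. Passing tests therefore demonstrate
correctness of the *analysis chain*, not robustness to everything real
infant EEG contains.

Group scenarios: the `exp1` scenario multiplies the duple-frequency
(1.5 Hz) mean by `boost_factor` in the music-class group; the `exp2`
scenario multiplies all tagged means in the parent-trained group. All
randomness flows from one master seed through `numpy.random.SeedSequence`,
so a cohort is bit-reproducible.

## Preprocessing

Order: band-pass → resample → artifact attenuation → common-average
reference → epoch averaging.

* Band-pass: 0.5 Hz high-pass and 20 Hz low-pass, each a 4th-order
  Butterworth applied forward-backward (zero phase — mandatory for
  phase-locked averaging). The corner frequencies are the published
  values; the realization is this package's choice.
* Resampling to 200 Hz by polyphase filtering; event indices remap by the
  rate ratio, rounding half-up.
* Artifact attenuation: samples exceeding a threshold (default 200 µV),
  expanded by a 10 ms guard, are replaced by linear interpolation across
  the flagged run. This is a deliberately simple threshold-interpolation
  scheme, named for what it does; it bounds residual excursions at the
  threshold rather than reconstructing the underlying signal.
* Common-average reference: subtract the instantaneous cross-channel mean.
* Trial averaging: epochs 1000–34000 ms after each trial onset, per-epoch
  baseline correction using the 900–1000 ms window (which precedes the
  epoch window; baseline correction is per epoch, from the continuous
  record), then the first 1000 ms of the average is discarded. The
  retained window is 2000–34000 ms = 32 s — an integer number of pattern
  cycles for both rhythms, so every tagged frequency falls on an exact DFT
  bin, and the spectral resolution is 1/32 s = 0.03125 Hz. Onsets whose
  windows leave the recording are skipped with a warning; zero usable
  epochs is an error.

## Steady-state amplitudes

Per channel, the averaged waveform is Fourier-transformed. The residual
background at each bin is estimated as the mean amplitude of the bins at
offsets ±3…±5 (six bins, ±0.094–0.156 Hz at the default resolution) and
subtracted; a symmetric neighbour set cancels any locally linear noise
floor exactly. Bins within five bins of a spectrum edge have no full
neighbour set and are marked invalid (NaN) rather than zeroed. Corrected
amplitudes are *not* clipped at zero, so the null distribution stays
centred on zero. Corrected spectra are averaged over all channels
(avoiding electrode selection), and the response at each frequency of
interest is the maximum within a 3-bin band centred on the nearest bin
(exact midpoints resolve toward the lower frequency — a documented
constant). The noise floor is the mean of the same 3-bin measure over the
control frequencies.

The 3-bin maximum is positively biased under the null (expectation of a
max of zero-mean values); unbiasedness of the noise subtraction is
therefore checked at the bin level (band of 1), while the pipeline reports
the 3-bin measure the published analysis used.

Outlier screening: each subject's mean corrected amplitude over the tagged
frequencies is z-scored across subjects (sample SD); |z| > 3 excludes the
subject (flagged, not dropped). Screening uses corrected amplitudes.

## Transient responses

Epochs −100…300 ms around selected tone onsets (the first tone of each
pattern cycle by default; a "first tone after a silence" selector is also
provided since both descriptions appear in the source material), baseline
−100…0 ms. Waveforms are pooled over eight frontal channels per hemisphere
(the montage's frontal-most rows; the specific channels are a config
input, since no published list exists — with fewer than 32 channels the
default groups span the whole schematic head and the dipolar topography
cancels, so small test montages pass an explicit smaller group). The
grand-average peak latency per hemisphere (largest absolute value,
searched 50–250 ms so the subsequent window fits the epoch; ties to the
earliest sample) fixes a ±50 ms window in which each subject's magnitude
is the signed trapezoidal area under the curve (µV·ms). Signed area is the
default because the modelled response is a dominant positive deflection; a
rectified variant is a config switch.

## Statistics

* Paired t (two-sided) with Bonferroni adjustment (`min(1, m·p)`);
  identical vectors return t = 0, p = 1.
* Mixed-design ANOVA (one between-subject, one repeated factor) via
  `pingouin.mixed_anova`; the Greenhouse–Geisser epsilon (from the
  double-centred covariance of the repeated measures, clamped to
  [1/(k−1), 1], exactly 1 for two levels) multiplies the within and
  interaction degrees of freedom, and corrected p-values are recomputed
  from the F distribution. The test suite checks all F statistics and
  epsilon against an independent sums-of-squares implementation to 1e-8.
* Pearson correlation with t-based two-sided p.
* The report layer assembles: tagged-vs-noise-floor paired t-tests
  (Bonferroni family = number of tagged frequencies), the
  beat/meter-related vs unrelated contrast, the group × frequency mixed
  ANOVA with per-frequency post-hoc contrasts (family-wise alpha 0.10 by
  default for that five-test family), the group × hemisphere ERP ANOVA,
  music-background correlations, and a plain-text exclusion log.

## Validation scenarios and problem sizes

The simulation defaults mirror the emulated studies (13 vs 46 subjects,
32 × 34 s trials, 1000 Hz). Validation and calibration runs use scaled
designs — typically 200 Hz recordings (making the resample step the
identity), 4–32 channels, 1–2 trials, and 10 subjects per group — chosen
so the whole suite and the acceptance script complete in minutes while
leaving every contract intact:

* zero-noise, transient-free subjects recover every tagged amplitude
  within 1 % end-to-end (the residual is the analytic pass-band ripple of
  the zero-phase filter, largest at 1 Hz next to the 0.5 Hz corner);
* with background noise at one tenth of the mean component amplitude, the
  median recovery error over 20 subjects stays below 5 %;
* 50 pink-noise-only subjects leave the corrected bin amplitudes within
  2 SE of zero at every tagged frequency;
* a duple-boost cohort (boost 3, between-subject SD 8 %, 10 + 10 subjects,
  1 µV transient) yields a significant GG-corrected interaction localised
  to the 1.5 Hz bin in ≳95 % of cohorts, while 200 null cohorts hold the
  interaction rate at the nominal alpha.

## Known limitations

* The attenuator bounds artifacts at the threshold; it does not
  reconstruct signal under an artifact, and its benefit is visible mainly
  for gross (≫ threshold) bursts — the neighbour-bin subtraction already
  absorbs much broadband burst energy.
* Steady-state and transient generators share spectral bins by
  construction; the package reports their sum, as scalp EEG does. Ground
  truth is only "clean" when one generator is switched off.
* The file formats are plain text (CSV + JSON sidecars, WAV for audio);
  there is no native EEG-vendor format support.
* No topographic mapping, source localisation or phase analysis.
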