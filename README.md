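# rhythmtag

EEG frequency-tagging analysis of neural entrainment to musical rhythm —
for researchers who want the full analysis chain used in infant
steady-state evoked-potential (SS-EP) studies as tested, reproducible
code, exercised end to end on a synthetic-EEG generator with known ground
truth.

## The problem and the method

When a listener hears a rhythm built on an isochronous pulse (here 333 ms
inter-onset interval, i.e. a 3 Hz beat), the EEG develops narrow-band
responses *phase-locked to the stimulus*: spectral peaks at the beat
frequency and at subharmonics corresponding to how beats are grouped into
meter (duple 1.5 Hz, triple 1 Hz, quadruple 0.75 Hz). Frequency tagging
identifies these responses by the exact frequencies the stimulus imposes.

The pipeline:

1. **Stimulus** — synthesize the rhythm (990 Hz tones, 10 ms ramps),
   extract its Hilbert amplitude envelope, and take the envelope's DFT.
   The stimulus-present frequencies (and a control grid between them)
   follow automatically from this spectrum.
2. **Preprocess** — 0.5–20 Hz zero-phase band-pass, resample to 200 Hz,
   threshold-interpolation artifact attenuation, common-average reference,
   trial averaging (epochs 1000–34000 ms, 900–1000 ms baseline, first
   second discarded → a 32 s window, resolution 1/32 Hz).
3. **SS-EP** — per-channel FFT of the averaged waveform; noise-floor
   subtraction using the mean of the bins at offsets ±3…±5 around each
   bin; averaging of corrected spectra over all channels; response = max
   within a 3-bin band at each tagged frequency f:

        A_corr(f) = A(f) − mean{ A(f + k·Δf) : k = ±3, ±4, ±5 },  Δf = 1/32 Hz

4. **ERP** — epochs −100…300 ms around the first tone of each rhythm
   cycle, eight-channel frontal groups per hemisphere, grand-average peak
   latency, and each subject's area under the curve over ±50 ms around it.
5. **Statistics** — paired t-tests vs the noise floor (Bonferroni),
   beat/meter vs unrelated contrasts, mixed group × frequency ANOVA with
   Greenhouse–Geisser correction, Pearson correlations with
   music-background measures, ±3 z-score outlier screening.

No public infant EEG accompanies the emulated studies, so the
`rhythmtag.simulate` module generates recordings with the statistical
structure the analysis assumes — phase-locked sinusoids with smooth scalp
topographies, a tone-locked transient, 1/f noise, burst artifacts, and
per-subject group structure — with every ground-truth value retrievable.

## Worked example

```python
from rhythmtag import RunConfig
from rhythmtag.pipeline import analyze_cohort

cfg = RunConfig.preset_exp1(seed=11, erp_channels_per_side=4, cohort=dict(
    n_subjects={"music": 10, "no_music": 10}, n_trials=2, n_channels=16,
    rate_hz=200.0, noise_level_uv=2.0, ssep_sd_frac=0.08, boost_factor=3.0,
    erp_amp_uv=1.0, erp_amp_sd_uv=0.3,
))
res = analyze_cohort(cfg, out_dir="run_exp1")
print(res["report"]["group_by_frequency_anova"].round(4))
```

This simulates a scaled cohort in which the music-class group's
duple-meter (1.5 Hz) amplitude is boosted threefold, runs the full chain,
and prints:

```
        effect         F     df1      df2    p  gg_epsilon
0        group   30.0043  1.0000  18.0000  0.0         NaN
1    frequency  110.0039  1.4217  25.5907  0.0      0.3554
2  interaction   53.2223  1.4217  25.5907  0.0      0.3554
```

— a significant group × frequency interaction (degrees of freedom carry
the Greenhouse–Geisser epsilon 0.3554). The post-hoc table in
`res["report"]["posthoc_group_by_frequency"]` localises the group
difference to the 1.5 Hz bin alone (t(18) = 11.53, Bonferroni p < 1e-4;
all other frequencies p ≈ 1), i.e. the analysis recovers exactly the
frequency-specific effect that was built into the simulation.

The numbered scripts under `analysis/` run the same machinery as narrative
steps (stimulus spectra → recovery validation → the two cohort analyses →
null calibration), each writing its tables under `results/`.

There is also a CLI:

```
rhythmtag stimulus --preset exp1 --out stim/       # envelope spectrum + frequency sets
rhythmtag run-all --preset exp1 --seed 1 --out run/ --subjects 8 --trials 2 --channels 16
```

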