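#!/usr/bin/env python
"""Validate that the preprocessing + spectral chain recovers known
steady-state amplitudes from simulated recordings.

Finding: at zero noise every tagged amplitude is recovered within ~0.5 %
(the residual is the analytic pass-band ripple of the 0.5-20 Hz zero-phase
filter); with background noise at one tenth of the mean component
amplitude the median error across 20 subjects stays well below 5 %.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rhythmtag import RunConfig
from rhythmtag.pipeline import derive_frequencies, preprocess_recording, subject_ssep
from rhythmtag.simulate import SubjectMeta, simulate_subject

OUT = Path(__file__).resolve().parent.parent / "results"
META = SubjectMeta("S0", "music", True, 6.0, 5.0, 7.0)


def cfg_for(seed, noise):
    return RunConfig.preset_exp1(seed=seed, cohort=dict(
        n_subjects={"music": 2, "no_music": 2}, n_trials=2, n_channels=4,
        rate_hz=200.0, noise_level_uv=noise, ssep_sd_frac=0.0,
        erp_amp_uv=0.0, erp_amp_sd_uv=0.0,
    ))


freqs = derive_frequencies(cfg_for(0, 0.0))
rows = []
for label, noise, seeds in [("zero_noise", 0.0, [0]), ("snr_10", 0.021, range(20))]:
    for seed in seeds:
        cfg = cfg_for(seed, noise)
        rec, truth = simulate_subject(cfg.cohort, META, seed)
        res = subject_ssep(preprocess_recording(rec, cfg), cfg, freqs)
        for f, a in truth.ssep_amp_uv.items():
            rows.append({"condition": label, "seed": seed, "frequency_hz": f,
                         "true_uv": a, "recovered_uv": res.amp_by_freq[f],
                         "rel_error_pct": abs(res.amp_by_freq[f] - a) / a * 100})
df = pd.DataFrame(rows)
df.to_csv(OUT / "recovery.csv", index=False)
for label, g in df.groupby("condition"):
    print(f"{label}: max error {g.rel_error_pct.max():.3f} %, "
          f"median {g.rel_error_pct.median():.3f} % over {g.seed.nunique()} subject(s)")
print(f"table: {OUT / 'recovery.csv'}")
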