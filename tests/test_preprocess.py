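"""Filtering, resampling, artifact attenuation, referencing, epoching."""

import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from conftest import tiny_exp1
from rhythmtag.preprocess import (
    attenuate_artifacts,
    bandpass,
    epoch_average,
    rereference_common_average,
    resample,
)
from rhythmtag.pipeline import preprocess_recording, subject_ssep
from rhythmtag.simulate import EEGRecording, SubjectMeta, simulate_subject


def make_rec(data, rate=1000.0, events=()):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = [f"C{i}" for i in range(data.shape[0])]
    return EEGRecording(data, rate, labels, list(events))


def filtfilt_gain(f, rate, hp=0.5, lp=20.0):
    """Analytic passband gain of the 4th-order Butterworth pair applied
    forward-backward (|H|^2)."""
    w = 2 * np.pi * f / rate
    g = 1.0
    for sos in (
        butter(4, hp, btype="highpass", fs=rate, output="sos"),
        butter(4, lp, btype="lowpass", fs=rate, output="sos"),
    ):
        _, h = sosfreqz(sos, worN=[w])
        g *= np.abs(h[0]) ** 2
    return g


class TestBandpass:
    def test_dc_rejected(self):
        rec = make_rec(np.full((2, 4000), 50.0))
        out = bandpass(rec, 0.5, 20.0)
        assert np.abs(out.data.mean()) < 1e-3 * 50.0

    @pytest.mark.parametrize("f,spec_bound", [(3.0, 0.05), (40.0, None)])
    def test_gain_matches_analytic_response(self, f, spec_bound):
        rate = 1000.0
        t = np.arange(0, 30, 1 / rate)
        rec = make_rec(np.sin(2 * np.pi * f * t))
        out = bandpass(rec, 0.5, 20.0)
        # the 0.5 Hz high-pass transient decays over seconds; measure at the
        # centre, far from both edges
        mid = slice(14000, -14000)
        measured = np.abs(out.data[0, mid]).max()
        expected = filtfilt_gain(f, rate)
        assert measured == pytest.approx(expected, rel=0.02)
        if spec_bound is not None:  # passband: amplitude preserved
            assert abs(measured - 1.0) < spec_bound
        else:  # stopband: >= 20 dB down
            assert measured < 10 ** (-20 / 20)

    def test_invalid_corners(self):
        rec = make_rec(np.zeros((1, 100)), rate=100.0)
        with pytest.raises(ValueError):
            bandpass(rec, 20.0, 0.5)
        with pytest.raises(ValueError):
            bandpass(rec, 0.5, 60.0)


class TestResample:
    def test_sample_count_1000_to_200(self):
        rec = make_rec(np.zeros((3, 34000)), rate=1000.0)
        out = resample(rec, 200.0)
        assert out.data.shape == (3, 6800)
        assert out.rate_hz == 200.0

    def test_identity_rate(self):
        rec = make_rec(np.arange(100.0))
        out = resample(rec, 1000.0)
        assert np.array_equal(out.data, rec.data)

    def test_inband_sinusoid_preserved(self):
        rate = 1000.0
        t = np.arange(0, 30, 1 / rate)
        rec = make_rec(np.sin(2 * np.pi * 3.0 * t))
        out = resample(rec, 200.0)
        mid = slice(1000, -1000)
        assert np.abs(out.data[0, mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_event_remapping_rounds_half_up(self):
        rec = make_rec(np.zeros((1, 1000)), events=[(502, "x"), (500, "y")])
        out = resample(rec, 200.0)
        assert dict((c, s) for s, c in out.events) == {"x": 100, "y": 100}

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(make_rec(np.zeros((1, 100))), 2000.0)


class TestAttenuateArtifacts:
    def test_clean_recording_unchanged(self):
        rng = np.random.default_rng(0)
        rec = make_rec(50 * rng.standard_normal((2, 2000)))
        rec.data.clip(-190, 190, out=rec.data)
        out = attenuate_artifacts(rec, 200.0)
        assert np.array_equal(out.data, rec.data)

    def test_burst_removed_below_threshold(self):
        data = np.zeros((2, 2000))
        data[0, 800:900] = 500.0
        out = attenuate_artifacts(make_rec(data), 200.0)
        assert np.all(np.abs(out.data) <= 200.0)
        assert np.array_equal(out.data[1], data[1])

    def test_attenuation_improves_ssep_recovery(self, exp1_freqs):
        # A/B on simulated ground truth: bursts on vs attenuated
        cfg = tiny_exp1(
            noise_level_uv=0.1, ssep_mean_uv={1.5: 0.4}, ssep_sd_frac=0.0,
            erp_amp_uv=0.0, erp_amp_sd_uv=0.0,
            artifact_rate_hz=1.0 / 34.0, artifact_amp_uv=5000.0,
        )
        meta = SubjectMeta("S0", "music", True, 6.0, 5.0, 7.0)
        errs = {"with": [], "without": []}
        for seed in range(6):
            rec, truth = simulate_subject(cfg.cohort, meta, seed)
            for mode, thr in (("with", 200.0), ("without", 1e9)):
                from rhythmtag.preprocess import bandpass as bp

                out = bp(rec, 0.5, 20.0)
                out = attenuate_artifacts(out, thr)
                out = rereference_common_average(out)
                res = subject_ssep(out, cfg, exp1_freqs)
                errs[mode].append(
                    abs(res.amp_by_freq[1.5] - truth.ssep_amp_uv[1.5])
                )
        assert np.mean(errs["with"]) < np.mean(errs["without"])

    def test_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            attenuate_artifacts(make_rec(np.zeros((1, 10))), 0.0)


class TestCommonAverage:
    def test_per_sample_mean_vanishes(self):
        rng = np.random.default_rng(1)
        out = rereference_common_average(make_rec(rng.standard_normal((8, 500)) * 30))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_already_referenced_unchanged(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal((4, 100))
        d -= d.mean(axis=0, keepdims=True)
        out = rereference_common_average(make_rec(d))
        assert np.allclose(out.data, d, atol=1e-12)

    def test_antisymmetric_pair_unchanged(self):
        v = np.sin(np.linspace(0, 10, 200))
        out = rereference_common_average(make_rec(np.vstack([v, -v])))
        assert np.allclose(out.data, np.vstack([v, -v]))

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_common_average(make_rec(np.zeros((1, 10))))


class TestEpochAverage:
    def test_identical_epochs_average_to_one_epoch(self):
        rate = 200.0
        epoch = np.sin(2 * np.pi * 2 * np.arange(400) / rate)
        data = np.tile(epoch, 5)[None, :]
        onsets = np.arange(5) * 400
        avg = epoch_average(make_rec(data, rate), onsets, 0, 2000, 0, 100)
        base = epoch - epoch[:round(0.1 * rate)].mean()
        assert np.allclose(avg.data[0], base, atol=1e-12)
        assert avg.n_epochs_averaged == 5

    def test_noise_shrinks_as_inverse_sqrt_n(self):
        rate, n_len = 200.0, 400
        sds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_ep = 16
            data = rng.standard_normal((1, n_ep * n_len))
            onsets = np.arange(n_ep) * n_len
            avg = epoch_average(make_rec(data, rate), onsets, 0, 2000, 0, 100)
            sds.append(avg.data[0].std())
        expected = 1.0 / np.sqrt(16)
        assert np.mean(sds) == pytest.approx(expected, rel=0.2)

    def test_baseline_window_mean_removed(self):
        rate = 200.0
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, 2000)) + 5.0
        avg = epoch_average(make_rec(data, rate), [0], 0, 2000, 100, 200)
        b = avg.data[:, round(0.1 * rate):round(0.2 * rate)].mean(axis=1)
        assert np.abs(b).max() < 1e-12

    def test_edge_onsets_skipped_and_all_bad_is_error(self):
        rec = make_rec(np.zeros((1, 1000)), rate=200.0)
        avg = epoch_average(rec, [-100, 0], 0, 1000, 0, 100)
        assert avg.n_epochs_averaged == 1
        with pytest.raises(ValueError):
            epoch_average(rec, [-100], 0, 1000, 0, 100)

    def test_discard_first_removes_leading_window(self):
        rate = 200.0
        data = np.arange(400.0)[None, :]
        avg = epoch_average(make_rec(data, rate), [0], 0, 2000, 0, 1000, 1000)
        assert avg.t0_ms == 1000
        assert avg.data.shape[1] == 200


class TestPipelineLinearity:
    def test_rereference_commutes_with_epoch_average(self, exp1_freqs):
        # artifact-free input: channel-averaged SS-EP amplitudes identical
        # whether CAR is applied before or after trial averaging
        from rhythmtag.preprocess import bandpass as bp, resample as rs
        from rhythmtag.pipeline import subject_ssep

        cfg = tiny_exp1(noise_level_uv=1.0, n_trials=2)
        meta = SubjectMeta("S0", "music", True, 6.0, 5.0, 7.0)
        rec, _ = simulate_subject(cfg.cohort, meta, 9)
        filt = rs(bp(rec, 0.5, 20.0), 200.0)

        res_before = subject_ssep(rereference_common_average(filt), cfg, exp1_freqs)

        # CAR after epoching == epoching CAR'd data, by linearity; emulate by
        # averaging first on unreferenced data then re-referencing the average
        from rhythmtag.preprocess import epoch_average as ea

        avg = ea(filt, filt.event_samples("trial_start"), 1000, 34000, 900, 1000, 1000)
        avg.data -= avg.data.mean(axis=0, keepdims=True)
        from rhythmtag import ssep as sp

        spectra = [sp.subtract_noise(s) for s in sp.spectrum_per_channel(avg)]
        mean_spec = sp.average_across_channels(spectra)
        for f in exp1_freqs.stimulus_present_hz:
            assert sp.peak_amplitude(mean_spec, f) == pytest.approx(
                res_before.amp_by_freq[f], abs=1e-9
            )
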