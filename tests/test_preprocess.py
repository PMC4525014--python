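"""Signal conditioning: filtering, re-referencing, ocular removal, epoching."""

import dataclasses

import numpy as np
import pytest

from skerp import synth_cohort as sc
from skerp.eeg_io import DEFAULT_CHANNELS, EEGRecording
from skerp.preprocess import (bandpass_filter, baseline_correct,
                              extract_epochs, infomax_ica,
                              rereference_avg_mastoids, reject_artifacts,
                              remove_ocular)

from conftest import make_trials

FS = 500.0


def recording_from(data, events=(), channels=None):
    return EEGRecording(list(channels or DEFAULT_CHANNELS), FS,
                        np.asarray(data, float), list(events))


def flat_recording(n=6000, events=()):
    return recording_from(np.zeros((len(DEFAULT_CHANNELS), n)), events)


class TestBandpass:
    def _sine_response(self, freq, n=20000):
        t = np.arange(n) / FS
        data = np.zeros((len(DEFAULT_CHANNELS), n))
        data[0] = np.sin(2 * np.pi * freq * t)
        out = bandpass_filter(recording_from(data))
        mid = slice(n // 4, 3 * n // 4)  # steady state
        return out.data[0][mid], np.sin(2 * np.pi * freq * t)[mid]

    def test_passband_identity_at_10_hz(self):
        y, x = self._sine_response(10.0)
        amp = y.max()
        assert 0.95 <= amp <= 1.0
        # phase: cross-correlation peak at zero lag
        lag = np.argmax(np.correlate(y, x, "full")) - (len(x) - 1)
        assert lag == 0

    def test_stopband_attenuation_at_50_hz(self):
        # two passes of an order-2 band-pass: |H(50)|^2 < 0.2 with a 30 Hz edge
        y, _ = self._sine_response(50.0)
        assert y.max() < 0.2

    def test_zero_phase_impulse_symmetry(self):
        # long record so the slow 0.2 Hz tail decays before the edges
        n = 60001
        data = np.zeros((len(DEFAULT_CHANNELS), n))
        data[0, n // 2] = 1.0
        out = bandpass_filter(recording_from(data)).data[0]
        mirrored = out[::-1]
        core = slice(n // 4, 3 * n // 4)
        assert np.max(np.abs(out[core] - mirrored[core])) < 1e-8

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(flat_recording(), low=0.2, high=300.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = recording_from(rng.normal(size=(len(DEFAULT_CHANNELS), 4000)))
        b = recording_from(rng.normal(size=(len(DEFAULT_CHANNELS), 4000)))
        mix = recording_from(2.0 * a.data + 3.0 * b.data)
        out_mix = bandpass_filter(mix).data
        out_sep = 2.0 * bandpass_filter(a).data + 3.0 * bandpass_filter(b).data
        assert np.allclose(out_mix, out_sep, atol=1e-9)


class TestRereference:
    def test_zero_mastoid_is_identity(self):
        rng = np.random.default_rng(1)
        rec = recording_from(rng.normal(size=(len(DEFAULT_CHANNELS), 1000)))
        rec.data[rec.ch_index("M2")] = 0.0
        out = rereference_avg_mastoids(rec)
        for ch in ("Fz", "FCz", "Pz"):
            assert np.array_equal(out.get(ch), rec.get(ch))
        assert out.reference == "averaged_mastoids"

    def test_constant_mastoid_shifts_scalp_by_half(self):
        rec = flat_recording(1000)
        rec.data[rec.ch_index("M2")] = 2.0
        out = rereference_avg_mastoids(rec)
        for ch in ("Fz", "C3", "P4"):
            assert np.allclose(out.get(ch), -1.0)
        for ch in ("HEOGL", "VEOGU"):
            assert np.allclose(out.get(ch), 0.0)

    def test_symmetric_mastoid_signal_vanishes_from_scalp(self):
        # a source injected equally at both mastoids appears on every
        # left-mastoid-referenced scalp channel as -s and on M2 as 0;
        # wait -- construct explicitly: scalp_i = brain_i + s_common - s_common
        t = np.arange(2000) / FS
        common = 5.0 * np.sin(2 * np.pi * 3 * t)
        rec = flat_recording(2000)
        # online reference = left mastoid = common; recorded channel = true - M1
        for ch in rec.ch_names:
            i = rec.ch_index(ch)
            if ch == "M2":
                rec.data[i] = common - common  # M2 - M1 = 0
            elif ch not in ("HEOGL", "HEOGR", "VEOGU", "VEOGD"):
                rec.data[i] = 0.0 - common  # brain-silent scalp site
        out = rereference_avg_mastoids(rec)
        # after averaged-mastoids re-reference the common source remains
        # (it is a reference property): x' = (0 - common) - 0/2
        assert np.allclose(out.get("Fz"), -common)

    def test_missing_mastoid_raises(self):
        chans = [c for c in DEFAULT_CHANNELS if c != "M2"]
        rec = recording_from(np.zeros((len(chans), 100)), channels=chans)
        with pytest.raises(ValueError):
            rereference_avg_mastoids(rec)


class TestOcularRemoval:
    def test_silent_eog_identity(self):
        rng = np.random.default_rng(2)
        rec = recording_from(rng.normal(size=(len(DEFAULT_CHANNELS), 5000)))
        for ch in ("HEOGL", "HEOGR", "VEOGU", "VEOGD"):
            rec.data[rec.ch_index(ch)] = 0.0
        for method in ("regression", "infomax"):
            out = remove_ocular(rec, method=method)
            assert np.array_equal(out.data, rec.data)

    @pytest.mark.parametrize("method", ["regression", "infomax"])
    def test_blink_leakage_removed(self, method, base_spec):
        spec = dataclasses.replace(base_spec, noise_sd=3.0, blink_rate=30.0)
        trials = make_trials(["hit"] * 40, np.full(40, 0.85))
        rec = sc.generate_eeg(spec, trials)
        blink = rec.get("VEOGU") - rec.get("VEOGD")  # blink-dominated trace
        assert abs(np.corrcoef(rec.get("Fz"), blink)[0, 1]) > 0.5
        out = remove_ocular(rec, method=method, seed=4)
        assert abs(np.corrcoef(out.get("Fz"), blink)[0, 1]) < 0.1

    def test_infomax_recovers_supergaussian_mixture(self):
        rng = np.random.default_rng(3)
        n = 20000
        S = np.vstack([rng.laplace(size=n),
                       (rng.random(n) < 0.01) * rng.normal(0, 8, n),
                       np.sinh(rng.standard_normal(n))])
        A = np.array([[1.0, 0.5, 0.3], [0.2, 1.0, 0.4], [0.3, 0.2, 1.0]])
        _, W, _, converged = infomax_ica(A @ S, seed=0)
        assert converged
        P = W @ A
        P = P / np.abs(P).max(axis=1, keepdims=True)
        perm = np.argmax(np.abs(P), axis=1)
        assert sorted(perm) == [0, 1, 2]  # one source per component
        off = np.abs(P).copy()
        off[np.arange(3), perm] = 0.0
        assert off.max() < 0.05

    def test_too_few_eog_channels_rejected(self):
        chans = ["F3", "Fz", "FCz", "M2", "VEOGU"]
        rec = recording_from(np.zeros((5, 100)), channels=chans)
        with pytest.raises(ValueError):
            remove_ocular(rec)


class TestEpochs:
    def _three_trial_recording(self):
        events = []
        for k, rel in enumerate((1000, 2200, 3400), start=1):
            events.append(("release", k, rel))
            events.append(("feedback", k, rel + 425))
        rng = np.random.default_rng(4)
        rec = recording_from(rng.normal(size=(len(DEFAULT_CHANNELS), 5000)),
                             events=events)
        return rec

    def test_release_epoch_sample_count(self):
        es = extract_epochs(self._three_trial_recording(), "release")
        assert es.epochs.shape == (3, len(DEFAULT_CHANNELS), 800)
        assert es.times[0] == pytest.approx(-0.6)

    def test_feedback_epoch_sample_count(self):
        es = extract_epochs(self._three_trial_recording(), "feedback")
        assert es.epochs.shape == (3, len(DEFAULT_CHANNELS), 900)

    def test_epoch_content_matches_continuous_slice(self):
        rec = self._three_trial_recording()
        ramp = np.arange(rec.n_samples, dtype=float)
        rec.data[rec.ch_index("FCz")] = ramp
        es = extract_epochs(rec, "release")
        i = es.ch_index("FCz")
        for k, rel in enumerate((1000, 2200, 3400)):
            assert np.array_equal(es.epochs[k, i],
                                  ramp[rel - 300: rel + 500])

    def test_out_of_bounds_epochs_dropped_and_logged(self):
        rec = self._three_trial_recording()
        rec.events.insert(0, ("release", 0, 100))  # window would start < 0
        rec.events.sort(key=lambda e: e[2])
        es = extract_epochs(rec, "release")
        assert es.n_epochs == 3
        assert es.rejection_log[0]["reason"] == "window_out_of_bounds"

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            extract_epochs(self._three_trial_recording(), "release",
                           window=(0.5, 0.5))

    def test_filter_then_epoch_commutes_with_epoch_then_filter(self):
        # conditioning the continuous record then slicing equals slicing a
        # pre-filtered record (away from record edges)
        rec = self._three_trial_recording()
        filtered = bandpass_filter(rec)
        es = extract_epochs(filtered, "release")
        es2 = extract_epochs(bandpass_filter(rec), "release")
        assert np.allclose(es.epochs, es2.epochs)


class TestBaselineAndRejection:
    def test_constant_epoch_becomes_zero(self):
        rec = flat_recording(events=[("release", 1, 1000)])
        rec.data[:] = 5.0
        es = baseline_correct(extract_epochs(rec, "release"))
        assert np.allclose(es.epochs, 0.0)

    def test_zero_mean_sine_unchanged(self):
        rec = flat_recording(events=[("release", 1, 1000)])
        t = np.arange(rec.n_samples) / FS
        # integer cycles over the 1.6 s epoch -> exactly zero mean
        rec.data[rec.ch_index("FCz")] = np.sin(2 * np.pi * 5.0 * (t - 1.4))
        es = extract_epochs(rec, "release")
        out = baseline_correct(es)
        i = es.ch_index("FCz")
        assert np.allclose(out.epochs[:, i], es.epochs[:, i], atol=1e-12)

    def test_random_epochs_zero_mean_variance_preserved(self):
        rng = np.random.default_rng(5)
        rec = recording_from(rng.normal(size=(len(DEFAULT_CHANNELS), 5000)),
                             events=[("release", 1, 1000),
                                     ("release", 2, 3000)])
        out = baseline_correct(extract_epochs(rec, "release"))
        assert np.abs(out.epochs.mean(axis=2)).max() < 1e-9
        raw = extract_epochs(rec, "release")
        assert np.allclose(out.epochs.var(axis=2), raw.epochs.var(axis=2))

    def test_clean_epochs_not_rejected(self):
        rng = np.random.default_rng(6)
        rec = recording_from(10.0 * rng.standard_normal(
            (len(DEFAULT_CHANNELS), 5000)) * 0.5,
            events=[("release", 1, 1000), ("release", 2, 3000)])
        es = reject_artifacts(extract_epochs(rec, "release"))
        assert es.n_epochs == 2
        assert es.rejection_log == []

    def test_amplitude_spike_rejected_exactly(self):
        rec = flat_recording(events=[("release", 1, 1000),
                                     ("release", 2, 3000)])
        rec.data[rec.ch_index("Cz"), 3100] = 150.0
        es = reject_artifacts(extract_epochs(rec, "release"))
        assert es.n_epochs == 1
        assert es.trial_ids.tolist() == [1]
        assert es.rejection_log[0] == {"trial": 2, "reason": "amplitude"}

    def test_gradient_criterion(self):
        rec = flat_recording(events=[("release", 1, 1000)])
        rec.data[rec.ch_index("Cz"), 1100:1102] = [0.0, 80.0]
        es = reject_artifacts(extract_epochs(rec, "release"))
        assert es.n_epochs == 0
        assert es.rejection_log[0]["reason"] == "gradient"

    def test_eog_spike_does_not_reject(self):
        rec = flat_recording(events=[("release", 1, 1000)])
        rec.data[rec.ch_index("VEOGU"), 1100] = 400.0
        es = reject_artifacts(extract_epochs(rec, "release"))
        assert es.n_epochs == 1

    def test_rejections_increase_with_blink_rate(self, base_spec):
        counts = []
        for rate in (0.0, 20.0, 60.0):
            spec = dataclasses.replace(base_spec, noise_sd=5.0,
                                       blink_rate=rate)
            trials = make_trials(["hit"] * 60, np.full(60, 0.85))
            rec = sc.generate_eeg(spec, trials)  # no ocular cleaning
            es = reject_artifacts(baseline_correct(
                extract_epochs(rec, "release")))
            counts.append(60 - es.n_epochs)
        assert counts[0] == 0
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]
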