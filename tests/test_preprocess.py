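"""ICA cleaning, epoch extraction and bandpass filtering."""

import logging

import numpy as np
import pytest

from fixfrp import preprocess, simulate
from fixfrp.gaze import Fixation
from fixfrp.preprocess import (
    Epoch,
    Recording,
    bandpass_epoch,
    epoch_length,
    extract_epochs,
    fit_ica,
    remove_components,
    select_artifact_components,
)


def _toy_recording(rng, n=20000, mixing=None):
    """Two super-Gaussian sources mixed into two EEG channels + 1 EOG channel."""
    S = rng.laplace(size=(2, n))
    A = np.array([[1.0, 0.5], [0.3, 1.0]]) if mixing is None else mixing
    X = A @ S
    data = np.vstack([X, rng.normal(size=(1, n))])
    rec = Recording(data, 256.0, ["c1", "c2", "e1"], ["EEG", "EEG", "EOG"])
    return rec, S, A


class TestICA:
    def test_recovers_known_super_gaussian_sources(self):
        rng = np.random.default_rng(0)
        rec, S, _ = _toy_recording(rng)
        model = fit_ica(rec, seed=0)
        acts = preprocess.ica_activations(model, rec)
        corr = np.abs(np.corrcoef(np.vstack([acts, S]))[:2, 2:])
        # up to permutation/scale each source matches one component
        assert corr.max(axis=0).min() > 0.95

    def test_identity_mixing_gives_permuted_identity(self):
        rng = np.random.default_rng(1)
        rec, S, _ = _toy_recording(rng, mixing=np.eye(2))
        model = fit_ica(rec, seed=1)
        W = model.unmixing / np.abs(model.unmixing).max(axis=1, keepdims=True)
        # each row ~ one-hot (up to sign): off-diagonal magnitude small
        for row in W:
            mags = np.sort(np.abs(row))[::-1]
            assert mags[0] == 1.0 and mags[1] < 0.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        rec, _, _ = _toy_recording(rng, n=6000)
        m1 = fit_ica(rec, seed=7)
        m2 = fit_ica(rec, seed=7)
        assert np.array_equal(m1.unmixing, m2.unmixing)

    def test_short_training_data_raises(self):
        rng = np.random.default_rng(3)
        rec, _, _ = _toy_recording(rng, n=50)
        with pytest.raises(ValueError, match="too short"):
            fit_ica(rec, seed=0)

    def test_rank_deficient_data_raises(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20000)
        data = np.vstack([x, 2 * x, rng.normal(size=20000)])
        rec = Recording(data, 256.0, ["c1", "c2", "e1"], ["EEG", "EEG", "EOG"])
        with pytest.raises(ValueError, match="rank"):
            fit_ica(rec, seed=0)

    def test_mixing_unmixing_identity(self):
        rng = np.random.default_rng(5)
        rec, _, _ = _toy_recording(rng, n=6000)
        model = fit_ica(rec, seed=0)
        assert np.allclose(model.mixing @ model.unmixing, np.eye(2), atol=1e-8)


class TestComponentSelection:
    def test_pure_eog_copy_component_is_flagged(self):
        # one EEG channel carries an exact copy of the EOG trace
        rng = np.random.default_rng(6)
        eog = rng.laplace(size=20000)
        other = rng.laplace(size=20000)
        data = np.vstack([eog + 0.05 * rng.normal(size=20000), other, eog])
        rec = Recording(data, 256.0, ["c1", "c2", "veog"], ["EEG", "EEG", "EOG"])
        model = fit_ica(rec, seed=0)
        flagged = select_artifact_components(model, rec)
        acts = preprocess.ica_activations(model, rec)
        cors = [abs(np.corrcoef(a, eog)[0, 1]) for a in acts]
        assert int(np.argmax(cors)) in flagged

    def test_artifact_free_recording_flags_nothing(self):
        # eog_artifact_gain = 0 everywhere and independent EOG noise:
        # across seeds, no component should correlate with EOG
        n_flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            S = rng.laplace(size=(2, 4000))
            data = np.vstack([S[0] + 0.2 * S[1], S[1], rng.normal(size=4000)])
            rec = Recording(data, 256.0, ["c1", "c2", "e1"], ["EEG", "EEG", "EOG"])
            model = fit_ica(rec, seed=seed)
            n_flagged += len(select_artifact_components(model, rec))
        assert n_flagged == 0

    def test_threshold_one_flags_only_exact_copies(self):
        rng = np.random.default_rng(7)
        rec, S, _ = _toy_recording(rng, n=6000)
        model = fit_ica(rec, seed=0)
        assert select_artifact_components(model, rec, corr_threshold=1.0) == set()

    def test_no_eog_channels_raises(self):
        rng = np.random.default_rng(8)
        data = rng.laplace(size=(2, 6000))
        rec = Recording(data, 256.0, ["c1", "c2"], ["EEG", "EEG"])
        model = fit_ica(rec, seed=0)
        with pytest.raises(ValueError):
            select_artifact_components(model, rec)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(9)
    rec, _, _ = _toy_recording(rng, n=6000)
    return rec, fit_ica(rec, seed=0)


class TestRemoval:
    def test_removing_nothing_is_identity(self, fitted):
        rec, model = fitted
        out = remove_components(rec, model, set())
        assert np.allclose(out.data, rec.data, atol=1e-8)

    def test_removing_everything_zeroes_eeg(self, fitted):
        rec, model = fitted
        out = remove_components(rec, model, {0, 1})
        # only the channel means remain
        assert np.allclose(out.eeg, out.eeg.mean(axis=1, keepdims=True), atol=1e-8)
        assert np.array_equal(out.eog, rec.eog)

    def test_out_of_range_index_raises(self, fitted):
        rec, model = fitted
        with pytest.raises(IndexError):
            remove_components(rec, model, {5})

    def test_saccade_artifact_removed_frp_retained(self):
        # generator ground truth: compare against an artifact-free twin built
        # from the identical random draws
        seed = 3
        cfg = simulate.reference_high_snr_config(seed=seed)
        rng = np.random.default_rng(seed)
        _, _, truth, rec = simulate.simulate_subject(cfg, rng)
        clean, model = preprocess.clean_recording(rec, seed=seed)
        assert len(model.removed) >= 1
        twin_cfg = simulate.reference_high_snr_config(seed=seed, saccade_artifact_uv=0.0)
        _, _, _, twin = simulate.simulate_subject(twin_cfg, np.random.default_rng(seed))
        fs = rec.fs
        sacc = []
        for i in range(len(truth) - 1):
            s0 = int(round((truth.onset_ms[i] + truth.duration_ms[i]) * fs / 1000))
            s1 = int(round(truth.onset_ms[i + 1] * fs / 1000))
            sacc.extend(range(s0, min(s1, rec.n_samples)))
        sacc = np.array(sacc)
        before = np.mean((rec.eeg[:, sacc] - twin.eeg[:, sacc]) ** 2)
        after = np.mean((clean.eeg[:, sacc] - twin.eeg[:, sacc]) ** 2)
        assert 1 - after / before >= 0.80
        # injected component amplitude retained within 10 %: average target
        # epochs at Pz in the cleaned vs artifact-free recordings
        n_ep = epoch_length(fs)
        pz = rec.channel_names.index("Pz")
        onsets = truth.frp_onset_samples[truth.label == "target"]
        onsets = onsets[onsets + n_ep < rec.n_samples]
        peak = int(round(cfg.frp_peak_latency_ms * fs / 1000))
        amp_clean = np.mean([clean.data[pz, o : o + n_ep] for o in onsets], axis=0)[peak]
        amp_twin = np.mean([twin.data[pz, o : o + n_ep] for o in onsets], axis=0)[peak]
        injected = cfg.frp_amplitude_uv["target"] * cfg.topography["Pz"]
        assert abs(amp_clean - amp_twin) <= 0.10 * injected


class TestEpochs:
    def test_epoch_has_205_samples_at_256_hz(self):
        assert epoch_length(256.0) == 205
        rec = Recording(np.zeros((2, 1000)), 256.0, ["a", "b"], ["EEG", "EEG"])
        fix = [Fixation(100.0, 200.0, (0, 0), 10, "target")]
        eps = extract_epochs(rec, fix)
        assert len(eps) == 1
        assert eps[0].data.shape == (2, 205)
        assert eps[0].label == "target"

    def test_fixation_at_recording_end_dropped_with_warning(self, caplog):
        rec = Recording(np.zeros((1, 300)), 256.0, ["a"], ["EEG"])
        fix = [Fixation(300 / 256 * 1000 - 1, 100.0, (0, 0), 5, "target")]
        with caplog.at_level(logging.WARNING):
            eps = extract_epochs(rec, fix)
        assert eps == []
        assert any("dropped" in r.message for r in caplog.records)

    def test_constant_recording_gives_constant_epochs(self):
        rec = Recording(np.full((2, 1000), 3.5), 256.0, ["a", "b"], ["EEG", "EEG"])
        eps = extract_epochs(rec, [Fixation(0.0, 100.0, (0, 0), 5, "x")])
        assert np.all(eps[0].data == 3.5)

    def test_epoch_count_matches_fixations_minus_drops(self, small_subject, small_config):
        _, _, truth, rec = small_subject
        fix = [
            Fixation(o, d, (0, 0), 5, l)
            for o, d, l in zip(truth.onset_ms, truth.duration_ms, truth.label)
        ]
        eps = extract_epochs(rec, fix)
        n_fit = sum(
            int(round(o * rec.fs / 1000)) + epoch_length(rec.fs) <= rec.n_samples
            for o in truth.onset_ms
        )
        assert len(eps) == n_fit


class TestBandpass:
    def _tone_epoch(self, freq, fs=256.0, amp=1.0):
        t = np.arange(epoch_length(fs)) / fs
        data = amp * np.sin(2 * np.pi * freq * t)[None, :]
        return Epoch(data=data, onset_sample=0, label="x", channel_names=["a"], fs=fs)

    def test_passband_tone_preserved(self):
        out = bandpass_epoch(self._tone_epoch(5.0))
        ratio = np.ptp(out.data) / np.ptp(self._tone_epoch(5.0).data)
        assert ratio > 0.95

    def test_stopband_tone_attenuated(self):
        out = bandpass_epoch(self._tone_epoch(50.0))
        assert out.data.std() <= 0.1 * self._tone_epoch(50.0).data.std()

    def test_dc_offset_removed(self):
        ep = Epoch(np.full((1, 205), 10.0), 0, "x", channel_names=["a"], fs=256.0)
        out = bandpass_epoch(ep)
        assert np.abs(out.data.mean()) <= 0.01 * 10.0

    def test_linearity(self):
        a, b = self._tone_epoch(3.0), self._tone_epoch(7.0)
        combo = Epoch(2 * a.data + 3 * b.data, 0, "x", channel_names=["a"], fs=256.0)
        lhs = bandpass_epoch(combo).data
        rhs = 2 * bandpass_epoch(a).data + 3 * bandpass_epoch(b).data
        assert np.allclose(lhs, rhs, atol=1e-4)

    def test_invalid_cutoffs_raise(self):
        with pytest.raises(ValueError):
            bandpass_epoch(self._tone_epoch(5.0), lo=10.0, hi=5.0)
        with pytest.raises(ValueError):
            bandpass_epoch(self._tone_epoch(5.0), lo=0.5, hi=200.0)


class TestEpochIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        eps = [
            Epoch(rng.normal(size=(2, 205)), 0, lab, "S00", ["a", "b"], 256.0)
            for lab in ("target", "background")
        ]
        preprocess.write_epochs_h5(eps, tmp_path / "ep.h5")
        back = preprocess.read_epochs_h5(tmp_path / "ep.h5")
        assert len(back) == 2
        assert np.allclose(back[0].data, eps[0].data)
        assert back[1].label == "background"
        assert back[0].channel_names == ["a", "b"]
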