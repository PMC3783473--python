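"""SSVEP decoding pipeline: preprocessing, MEC filtering, SNR scoring."""

import dataclasses

import numpy as np
import pytest
from scipy import signal

from spellersim import paradigms, ssvep, synthetic
from spellersim.paradigms import SSVEPSpellerConfig
from spellersim.ssvep import (
    FrequencyScoreSet,
    build_mec_filter,
    classify_window,
    decide_quadrant,
    preprocess_ssvep,
    score_frequencies,
    sinusoid_basis,
    spell_symbol,
)
from spellersim.synthetic import EEGRecording, SSVEPGenConfig

CH = synthetic.SSVEP_CHANNELS
CANDIDATES = (6.67, 7.5, 8.57, 10.0)


def _rec(data, fs=250.0):
    data = np.atleast_2d(data)
    return EEGRecording(data, fs, CH[: data.shape[0]])


class TestPreprocess:
    def test_50hz_attenuated_30db(self):
        t = np.arange(int(8 * 1000)) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 50 * t), fs=1000.0)
        out = preprocess_ssvep(rec)
        mid = out.data[0, 300:-300]
        atten_db = 20 * np.log10(np.abs(mid).max())
        assert atten_db < -30

    def test_slow_drift_removed(self):
        t = np.arange(int(8 * 1000)) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 1 * t), fs=1000.0)
        out = preprocess_ssvep(rec)
        # two-pass 4th-order high-pass at 4 Hz: |H(1 Hz)|^2 ~ (1/4)^8
        assert np.abs(out.data[0, 300:-300]).max() < 0.01

    def test_10hz_tone_preserved_at_250hz(self):
        t = np.arange(int(8 * 1000)) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 10 * t), fs=1000.0)
        out = preprocess_ssvep(rec)
        assert out.fs == 250.0
        mid = out.data[0, 300:-300]
        assert mid.std() * np.sqrt(2) == pytest.approx(1.0, abs=0.05)


class TestMEC:
    def test_noisy_channel_downweighted(self):
        rng = np.random.default_rng(0)
        data = 0.1 * rng.standard_normal((8, 1000))
        data[3] += 20.0 * rng.standard_normal(1000)  # one loud channel
        bank = build_mec_filter(_rec(data), CANDIDATES)
        w0 = np.abs(bank.weights[:, 0]) / np.abs(bank.weights[:, 0]).max()
        assert w0[3] < 0.05

    def test_white_noise_full_retention_keeps_all_components(self):
        rng = np.random.default_rng(1)
        bank = build_mec_filter(_rec(rng.standard_normal((8, 1000))),
                                CANDIDATES, retention=1.0)
        assert bank.n_components == 8

    def test_noise_energies_ascending_and_reduced(self):
        rng = np.random.default_rng(2)
        data = synthetic.pink_noise(rng, 8, 2000, 3.0)
        bank = build_mec_filter(_rec(data), CANDIDATES)
        assert (np.diff(bank.noise_energies) >= 0).all()
        # retained residual-noise energy per component is below the mean
        # channel noise energy before filtering
        mean_channel = (data**2).sum(axis=1).mean()
        assert bank.noise_energies.mean() <= mean_channel

    def test_projection_never_increases_energy(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((1000, 8))
        basis = sinusoid_basis(10.0, 2, 1000, 250.0)
        resid = ssvep._project_out(X, basis)
        assert (resid**2).sum() <= (X**2).sum()


class TestScoring:
    def test_pure_tone_wins_its_candidate(self):
        cfg = SSVEPGenConfig(frequency=10.0, harmonic_amplitudes=(2.0, 1.0),
                             noise_sigma=0.05, line_noise_amplitude=0.0, seed=4)
        rec = generate = synthetic.generate_ssvep_trial(cfg, 4.0, fs=250.0)
        scores = score_frequencies(rec.data, 250.0, CANDIDATES)
        assert scores.argmax == CANDIDATES.index(10.0)

    def test_scale_invariance_of_decision(self):
        rng = np.random.default_rng(5)
        data = synthetic.pink_noise(rng, 8, 1000, 2.0)
        s1 = score_frequencies(data, 250.0, CANDIDATES)
        s2 = score_frequencies(1e3 * data, 250.0, CANDIDATES)
        assert s1.argmax == s2.argmax
        assert np.allclose(s1.scores, s2.scores, rtol=1e-9)

    def test_phase_invariance(self):
        t = np.arange(1000) / 250.0
        scores = []
        for phi in (0.0, 1.1, 2.5):
            x = np.sin(2 * np.pi * 8.57 * t + phi) + 0.01 * np.sin(2 * np.pi * 30 * t)
            s = score_frequencies(x[None, :], 250.0, CANDIDATES)
            scores.append(s.scores[CANDIDATES.index(8.57)])
        assert np.allclose(scores, scores[0], rtol=0.05)

    def test_longer_window_scores_true_frequency_higher_on_average(self):
        """SNR estimator consistency: mean true-frequency score grows with
        window length (matched trials, nested windows)."""
        sums = {2: 0.0, 4: 0.0, 10: 0.0}
        n_trials = 12
        for i in range(n_trials):
            cfg = SSVEPGenConfig(frequency=10.0, seed=600 + i)
            rec = synthetic.generate_ssvep_trial(cfg, 10.0, fs=250.0)
            for dur in sums:
                win = rec.data[:, : int(dur * 250)]
                bank = build_mec_filter(_rec(win), CANDIDATES)
                s = score_frequencies(bank.apply(win), 250.0, CANDIDATES)
                sums[dur] += s.scores[CANDIDATES.index(10.0)]
        assert sums[2] < sums[4] < sums[10]


class TestDecision:
    def test_argmax(self):
        s = FrequencyScoreSet(CANDIDATES, np.array([1.0, 2.0, 3.0, 4.0]))
        assert decide_quadrant(s) == 3

    def test_tie_breaks_to_lowest_index(self):
        s = FrequencyScoreSet(CANDIDATES, np.ones(4))
        assert decide_quadrant(s) == 0

    def test_high_snr_window_classified_correctly(self):
        for j, f in enumerate(CANDIDATES):
            cfg = SSVEPGenConfig(frequency=f, harmonic_amplitudes=(4.0, 1.5),
                                 noise_sigma=1.0, seed=7 + j)
            rec = synthetic.generate_ssvep_trial(cfg, 4.0, fs=250.0)
            assert classify_window(rec, SSVEPSpellerConfig()) == j


class TestSpelling:
    def test_three_correct_decisions_reach_ground_truth(self):
        cfg = SSVEPSpellerConfig(level_duration_s=3.0)
        gen = SSVEPGenConfig(harmonic_amplitudes=(5.0, 2.0), noise_sigma=1.0,
                             line_noise_amplitude=0.0, seed=8)
        rec, events, truth = synthetic.generate_ssvep_speller_session(
            gen, cfg, "z"
        )
        decoded = ssvep.decode_session(rec, events, cfg)
        assert decoded == truth

    def test_missing_segment_rejected(self):
        cfg = SSVEPSpellerConfig()
        with pytest.raises(ValueError, match="3"):
            spell_symbol([_rec(np.zeros((8, 500)))] * 2, cfg)

    def test_symbol_accuracy_is_cubed_level_accuracy(self):
        """Independent levels at accuracy p give symbol accuracy p^3."""
        rng = np.random.default_rng(9)
        p = 0.8
        n = 20000
        levels = rng.random((n, 3)) < p
        sym_acc = levels.all(axis=1).mean()
        assert sym_acc == pytest.approx(p**3, abs=0.01)
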