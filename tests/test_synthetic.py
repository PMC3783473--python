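"""Synthetic EEG generator: determinism, event structure, spectra."""

import dataclasses

import numpy as np
import pytest
from scipy import signal

from spellersim import paradigms, ssvep, synthetic
from spellersim.synthetic import (
    ERPGenConfig,
    SSVEPGenConfig,
    generate_oddball_session,
    generate_p3_speller_session,
    generate_ssvep_speller_session,
    generate_ssvep_trial,
    pink_noise,
)


def test_oddball_session_counts_and_isi():
    cfg = ERPGenConfig(seed=4)
    rec, events = generate_oddball_session(cfg, 25, 275, stim_ms=100,
                                           isi_range_ms=(100, 300))
    assert len(events) == 300
    assert sum(e.is_target for e in events) == 25
    onsets = np.array([e.onset_sample for e in events])
    gaps = np.diff(onsets)  # stimulus + pause, in samples at 1 kHz
    assert gaps.min() >= 200 - 1 and gaps.max() <= 400 + 1
    assert rec.n_samples > onsets[-1] + 800


def test_seed_determinism_bit_identical():
    cfg = ERPGenConfig(seed=9)
    rec1, ev1 = generate_oddball_session(cfg, 5, 25)
    rec2, ev2 = generate_oddball_session(cfg, 5, 25)
    assert np.array_equal(rec1.data, rec2.data)
    assert ev1 == ev2
    t1 = generate_ssvep_trial(SSVEPGenConfig(seed=9), 2.0)
    t2 = generate_ssvep_trial(SSVEPGenConfig(seed=9), 2.0)
    assert np.array_equal(t1.data, t2.data)


def test_zero_amplitude_targets_equal_nontargets_in_mean():
    """With no P3, averaged target and non-target epochs differ only by noise."""
    cfg = ERPGenConfig(p3_amplitude=0.0, noise_sigma=5.0, seed=12)
    rec, events = generate_oddball_session(cfg, 150, 150)
    span = 800
    tgt = np.mean([rec.data[:, e.onset_sample:e.onset_sample + span]
                   for e in events if e.is_target], axis=0)
    non = np.mean([rec.data[:, e.onset_sample:e.onset_sample + span]
                   for e in events if not e.is_target], axis=0)
    # mean difference shrinks like sigma/sqrt(n); allow 5 SEs
    se = 5.0 * np.sqrt(2.0 / 150)
    assert np.abs(tgt - non).mean() < 5 * se


def test_target_epochs_carry_positive_bump():
    cfg = ERPGenConfig(p3_amplitude=6.0, noise_sigma=2.0, latency_jitter_sd=0.0,
                       seed=3)
    rec, events = generate_oddball_session(cfg, 40, 40)
    span = 800
    tgt = np.mean([rec.data[:, e.onset_sample:e.onset_sample + span]
                   for e in events if e.is_target], axis=0)
    peak_ms = tgt.mean(axis=0).argmax()
    assert 250 <= peak_ms <= 450  # bump peaks near the configured 350 ms


def test_nonfinite_config_rejected():
    with pytest.raises(ValueError):
        ERPGenConfig(p3_amplitude=float("nan"))
    with pytest.raises(ValueError):
        SSVEPGenConfig(noise_sigma=float("inf"))


def test_noiseless_ssvep_energy_confined_to_harmonics():
    cfg = SSVEPGenConfig(frequency=10.0, harmonic_amplitudes=(2.0, 1.0),
                         noise_sigma=0.0, line_noise_amplitude=0.0, seed=0)
    rec = generate_ssvep_trial(cfg, duration_s=2.0, fs=1000.0)
    oz = rec.data[rec.channels.index("Oz")]
    freqs = np.fft.rfftfreq(len(oz), 1 / rec.fs)
    amp = np.abs(np.fft.rfft(oz))
    harmonic = (np.abs(freqs - 10) < 0.5) | (np.abs(freqs - 20) < 0.5)
    # integer-cycle window: zero leakage outside the harmonic bins
    assert amp[~harmonic].max() < 1e-6 * amp.max()


def test_noisy_ssvep_dominant_peak_at_stimulation_frequency():
    cfg = SSVEPGenConfig(frequency=10.0, harmonic_amplitudes=(3.0, 1.0),
                         noise_sigma=2.0, seed=5)
    rec = generate_ssvep_trial(cfg, duration_s=10.0)
    oz = rec.data[rec.channels.index("Oz")]
    freqs, psd = signal.periodogram(oz, fs=rec.fs)
    band = (freqs > 4) & (freqs < 40)
    assert freqs[band][np.argmax(psd[band])] == pytest.approx(10.0, abs=0.2)


def test_line_noise_power_drops_after_notch():
    cfg = SSVEPGenConfig(harmonic_amplitudes=(0.0,), noise_sigma=1.0,
                         line_noise_amplitude=5.0, seed=6)
    rec = generate_ssvep_trial(cfg, duration_s=4.0)
    pre = ssvep.preprocess_ssvep(rec)

    def power_50(x, fs):
        freqs, psd = signal.periodogram(x, fs=fs)
        return psd[np.abs(freqs - 50).argmin()]

    before = power_50(rec.data[5], rec.fs)
    after = power_50(pre.data[5], pre.fs)
    assert after < 0.01 * before


def test_harmonic_above_nyquist_rejected():
    cfg = SSVEPGenConfig(frequency=30.0, harmonic_amplitudes=(1.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="Nyquist"):
        generate_ssvep_trial(cfg, 1.0, fs=100.0)


@pytest.mark.parametrize("style, expected", [
    ("row_column", 120), ("single_symbol", 360),
])
def test_p3_speller_session_event_counts(style, expected):
    isi = 100 if style == "row_column" else 0
    cfg = paradigms.P3SpellerConfig(style=style, stimulus_duration_ms=100,
                                    isi_ms=isi, repetitions=10)
    erp = ERPGenConfig(noise_sigma=1.0, seed=8)
    rec, events, truth = generate_p3_speller_session(erp, cfg, "Q")
    assert len(events) == expected
    assert truth == ["Q"]
    flags = cfg.target_codes("Q")
    assert sum(e.is_target for e in events) == 10 * len(flags)
    assert all((e.code in flags) == e.is_target for e in events)


def test_ssvep_speller_session_three_segments_per_symbol():
    cfg = paradigms.SSVEPSpellerConfig(level_duration_s=2.0)
    gen = SSVEPGenConfig(noise_sigma=1.0, seed=8)
    rec, events, truth = generate_ssvep_speller_session(gen, cfg, "A")
    assert len(events) == 3
    assert rec.n_samples == 3 * int(2.0 * rec.fs)
    path = paradigms.symbol_to_path(cfg, "A")
    assert tuple(e.code for e in events) == path


def test_empty_text_yields_empty_session():
    cfg = paradigms.P3SpellerConfig()
    rec, events, truth = generate_p3_speller_session(ERPGenConfig(), cfg, "")
    assert events == [] and truth == [] and rec.n_samples == 0


def test_decoder_accuracy_monotone_in_p3_amplitude():
    """Signal scaling: more ERP amplitude never hurts decoding.

    The noise realization is drawn before the bumps are injected, so
    sessions with the same seed are matched across amplitudes.
    """
    from spellersim import p3

    cfg = paradigms.P3SpellerConfig(repetitions=3)
    calib_cfg = dataclasses.replace(cfg, repetitions=10)
    erp = ERPGenConfig(p3_amplitude=8.0, seed=41)
    rng = np.random.default_rng(42)
    text = "".join(cfg.matrix[i] for i in rng.integers(0, 36, size=8))
    rec, events, _ = generate_p3_speller_session(erp, calib_cfg, text)
    model = p3.calibrate_from_session(rec, events, calib_cfg, seed=1)

    accs = []
    for amp in (0.0, 2.0, 4.0, 8.0, 16.0):
        correct = total = 0
        for c in range(2):
            words = "".join(cfg.matrix[i] for i in
                            np.random.default_rng(50 + c).integers(0, 36, 12))
            gen = dataclasses.replace(erp, p3_amplitude=amp, seed=60 + c)
            r2, e2, truth = generate_p3_speller_session(gen, cfg, words)
            dec = p3.decode_session(model, r2, e2, cfg)
            correct += sum(d == t for d, t in zip(dec, truth))
            total += len(truth)
        accs.append(correct / total)
    eps = 2 * np.sqrt(0.25 / total)
    assert all(b >= a - eps for a, b in zip(accs, accs[1:])), accs
    assert accs[-1] > accs[0]


def test_pink_noise_spectrum_slopes_down():
    rng = np.random.default_rng(0)
    x = pink_noise(rng, 1, 2**14, 1.0)[0]
    freqs, psd = signal.periodogram(x, fs=1000.0)
    low = psd[(freqs > 1) & (freqs < 10)].mean()
    high = psd[(freqs > 100) & (freqs < 200)].mean()
    assert low > 5 * high
    assert x.std() == pytest.approx(1.0, rel=0.05)
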