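"""P3 decoding pipeline: filtering, epoching, averaging, calibration, decoding."""

import dataclasses

import numpy as np
import pytest

from spellersim import p3, paradigms, synthetic
from spellersim.p3 import (
    EpochSet,
    average_by_code,
    calibrate,
    decode_symbol,
    epoch_and_downsample,
    preprocess_p3,
)
from spellersim.synthetic import EEGRecording, ERPGenConfig, StimulusEvent

FS = 1000.0
CH = synthetic.P3_CHANNELS


def _rec(data):
    return EEGRecording(np.atleast_2d(data), FS, CH[: np.atleast_2d(data).shape[0]])


class TestPreprocess:
    def test_50hz_strongly_attenuated(self):
        t = np.arange(int(4 * FS)) / FS
        rec = _rec(np.sin(2 * np.pi * 50 * t))
        out = preprocess_p3(rec)
        # measure the remaining 50 Hz component (the slow edge transient of
        # the 0.3 Hz corner is not line interference)
        mid = slice(1000, -1000)
        basis = np.column_stack([np.sin(2 * np.pi * 50 * t[mid]),
                                 np.cos(2 * np.pi * 50 * t[mid])])
        coef, *_ = np.linalg.lstsq(basis, out.data[0, mid], rcond=None)
        assert np.hypot(*coef) < 0.01  # < 1% of unit input amplitude

    def test_dc_offset_removed(self):
        rec = _rec(np.full(int(4 * FS), 37.0))
        out = preprocess_p3(rec)
        assert np.abs(out.data[0, 1000:-1000]).max() < 0.5

    def test_passband_tone_preserved_with_zero_lag(self):
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 5 * t)
        out = preprocess_p3(_rec(x)).data[0]
        mid = slice(2000, -2000)
        xc = np.correlate(out[mid], x[mid], mode="full")
        lag = xc.argmax() - (len(x[mid]) - 1)
        assert lag == 0  # zero-phase: no delay
        gain = out[mid].std() / x[mid].std()
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            preprocess_p3(_rec(np.zeros(10)))
        with pytest.raises(ValueError, match="sampling rate"):
            preprocess_p3(EEGRecording(np.zeros((1, 1000)), 100.0, ("Cz",)))


class TestEpoching:
    def test_shapes_and_feature_count(self):
        rec = EEGRecording(np.random.default_rng(0).normal(size=(8, 300 * 200 + 1000)),
                           FS, CH)
        events = [StimulusEvent(i * 200, i % 12, False) for i in range(300)]
        eps = epoch_and_downsample(rec, events)
        assert eps.epochs.shape == (300, 8, 80)
        assert eps.n_features == 640

    def test_out_of_bounds_event_reports_index(self):
        rec = EEGRecording(np.zeros((8, 1000)), FS, CH)
        events = [StimulusEvent(0, 0, False), StimulusEvent(999, 1, False)]
        with pytest.raises(ValueError, match="event 1"):
            epoch_and_downsample(rec, events)

    def test_synthetic_bump_peaks_at_sample_35(self):
        t_ms = np.arange(2000)
        bump = np.exp(-0.5 * ((t_ms - 350) / 40.0) ** 2)
        rec = EEGRecording(np.tile(bump, (8, 1)), FS, CH)
        eps = epoch_and_downsample(rec, [StimulusEvent(0, 0, True)])
        assert eps.epochs[0, 0].argmax() == 35  # 350 ms at 100 Hz


class TestAveraging:
    def _eps(self, epochs, codes):
        return EpochSet(np.asarray(epochs), 100.0, np.asarray(codes))

    def test_identical_epochs_average_to_themselves(self):
        e = np.ones((4, 2, 3))
        out = average_by_code(self._eps(e, [0, 0, 1, 1]), 2)
        assert np.allclose(out.epochs, 1.0)
        assert list(out.codes) == [0, 1]

    def test_noise_sd_shrinks_like_sqrt_repetitions(self):
        rng = np.random.default_rng(1)
        sigma, reps, n_mc = 2.0, 10, 1500
        e = rng.normal(0, sigma, size=(n_mc * reps, 1, 1))
        codes = np.repeat(np.arange(n_mc), reps)
        out = average_by_code(self._eps(e, codes), reps)
        sd = out.epochs.ravel().std()
        assert sd == pytest.approx(sigma / np.sqrt(reps), rel=0.1)

    def test_single_repetition_passthrough(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=(6, 2, 3))
        out = average_by_code(self._eps(e, [0, 0, 1, 1, 2, 2]), 1)
        assert np.array_equal(out.epochs, e[[0, 2, 4]])

    def test_insufficient_repetitions_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            average_by_code(self._eps(np.zeros((2, 1, 1)), [0, 1]), 2)


class TestCalibration:
    def _labelled(self, X, y):
        n = len(y)
        return EpochSet(X.reshape(n, 1, -1), 100.0, np.arange(n), y)

    def test_separable_classes_reach_full_cv_accuracy(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 20))
        y = np.r_[np.zeros(30, bool), np.ones(30, bool)]
        X[y] += 8.0
        model = calibrate(self._labelled(X, y), seed=0)
        assert model.cv_accuracy == 1.0

    def test_permuted_labels_give_chance_cv_accuracy(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 10))
        y = rng.permutation(np.r_[np.zeros(100, bool), np.ones(100, bool)])
        model = calibrate(self._labelled(X, y), seed=0)
        assert abs(model.cv_accuracy - 0.5) < 0.12  # ~3 binomial SEs

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            calibrate(self._labelled(np.zeros((10, 4)), np.zeros(10, bool)))

    def test_scores_are_affine_in_features(self, calibrated_model):
        rng = np.random.default_rng(5)
        x1, x2 = rng.normal(size=(2, 640))
        a = 0.3
        s = calibrated_model.score(np.vstack([x1, x2, a * x1 + (1 - a) * x2]))
        assert s[2] == pytest.approx(a * s[0] + (1 - a) * s[1], rel=1e-9)


class TestDecoding:
    def _crafted_eps(self, model, cfg, hot_codes):
        """Epochs whose scores are maximal exactly at ``hot_codes``."""
        n = cfg.n_stimuli
        feats = np.tile(model.feature_means, (n, 1))  # zero score after z-scoring
        w = model.weights / np.linalg.norm(model.weights) ** 2
        for c in hot_codes:
            feats[c] += 10.0 * w * model.feature_sds
        return EpochSet(feats.reshape(n, 8, 80), 100.0, np.arange(n))

    def test_row_column_intersection_rule(self, calibrated_model, rc_config):
        eps = self._crafted_eps(calibrated_model, rc_config, [2, 6 + 4])
        assert decode_symbol(calibrated_model, eps, rc_config) == \
            rc_config.symbol_at(2, 4)

    def test_single_symbol_argmax(self, calibrated_model):
        cfg = paradigms.P3SpellerConfig(style="single_symbol",
                                        stimulus_duration_ms=100, isi_ms=0)
        eps = self._crafted_eps(calibrated_model, cfg, [17])
        assert decode_symbol(calibrated_model, eps, cfg) == cfg.matrix[17]

    def test_missing_code_rejected(self, calibrated_model, rc_config):
        eps = EpochSet(np.zeros((11, 8, 80)), 100.0, np.arange(11))
        with pytest.raises(ValueError, match="missing"):
            decode_symbol(calibrated_model, eps, rc_config)

    def test_high_snr_end_to_end_recovers_text(self, calibrated_model,
                                               rc_config, high_snr_erp):
        erp = dataclasses.replace(high_snr_erp, seed=55)
        rec, events, truth = synthetic.generate_p3_speller_session(
            erp, rc_config, "BCI4"
        )
        decoded = p3.decode_session(calibrated_model, rec, events, rc_config)
        assert decoded == truth
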