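"""P300 matrix-speller decoding pipeline.

The chain is: zero-phase band-pass 0.3-15 Hz → 800 ms epochs from each
stimulus onset → downsample to 100 Hz (80 samples/channel, 640 features
on the 8-channel montage) → average epochs of the same stimulus code over
the repetitions used for spelling → score with a calibrated linear
max-margin classifier → pick the symbol at the intersection of the
best-scoring row and column (or the best-scoring symbol directly).

Calibration trains the classifier on supervised selections (known target
symbols), z-scoring features with calibration statistics and selecting
the regularization strength by stratified 10-fold cross-validation over a
logarithmic grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .paradigms import P3SpellerConfig, ROW_COLUMN
from .synthetic import EEGRecording, StimulusEvent

__all__ = [
    "EpochSet",
    "ERPModel",
    "preprocess_p3",
    "epoch_and_downsample",
    "average_by_code",
    "calibrate",
    "calibrate_from_session",
    "decode_symbol",
    "decode_session",
]

EPOCH_MS = 800.0
FS_OUT = 100.0


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``[n_trials, n_channels, n_samples]``.

    ``codes`` gives the stimulus code of each trial; ``labels`` the
    target/non-target ground truth where known (calibration/simulation).
    """

    epochs: np.ndarray
    fs_out: float
    codes: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be [n_trials, n_channels, n_samples]")
        self.codes = np.asarray(self.codes)
        if len(self.codes) != self.epochs.shape[0]:
            raise ValueError("one stimulus code per trial required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if len(self.labels) != self.epochs.shape[0]:
                raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_features(self) -> int:
        return self.epochs.shape[1] * self.epochs.shape[2]

    def features(self) -> np.ndarray:
        """Flattened [n_trials, n_channels * n_samples] feature matrix."""
        return self.epochs.reshape(self.n_trials, -1)


@dataclass
class ERPModel:
    """Trained linear decision rule with its normalization statistics.

    ``score(x) = (x - mean)/sd . weights + bias``; the score is the signed
    distance to the decision boundary (up to the weight norm), larger
    meaning more target-like.
    """

    weights: np.ndarray
    bias: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    regularization: float
    cv_accuracy: float = float("nan")

    def score(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(features)
        xn = (x - self.feature_means) / self.feature_sds
        return xn @ self.weights + self.bias


def preprocess_p3(rec: EEGRecording, band: tuple[float, float] = (0.3, 15.0),
                  order: int = 3) -> EEGRecording:
    """Zero-phase Butterworth band-pass of the raw recording.

    Forward-backward filtering doubles the attenuation and cancels the
    phase delay, preserving ERP latencies. Output length equals input
    length.
    """
    if rec.fs < 200:
        raise ValueError("sampling rate must be at least 200 Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if rec.n_samples <= padlen:
        raise ValueError("recording shorter than the filter warm-up")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(filtered, rec.fs, rec.channels)


def epoch_and_downsample(rec: EEGRecording, events: list[StimulusEvent],
                         epoch_ms: float = EPOCH_MS,
                         fs_out: float = FS_OUT) -> EpochSet:
    """Cut one epoch per event and decimate to ``fs_out``.

    Epochs span 0-``epoch_ms`` post-onset. Decimation keeps every
    ``fs/fs_out``-th sample; the preceding 0.3-15 Hz band-pass already
    guarantees anti-aliasing for the 100 Hz target rate.
    """
    step = rec.fs / fs_out
    if abs(step - round(step)) > 1e-9:
        raise ValueError("fs must be an integer multiple of the target rate")
    step = int(round(step))
    span = int(round(epoch_ms / 1000.0 * rec.fs))
    n_out = span // step
    epochs = np.empty((len(events), rec.n_channels, n_out))
    codes = np.empty(len(events), dtype=int)
    labels = np.empty(len(events), dtype=bool)
    for i, ev in enumerate(events):
        if ev.onset_sample < 0 or ev.onset_sample + span > rec.n_samples:
            raise ValueError(
                f"event {i} (onset sample {ev.onset_sample}) does not fit an "
                f"{epoch_ms:g} ms epoch inside the recording"
            )
        sl = rec.data[:, ev.onset_sample : ev.onset_sample + span]
        epochs[i] = sl[:, ::step]
        codes[i] = ev.code
        labels[i] = ev.is_target
    return EpochSet(epochs, fs_out, codes, labels)


def average_by_code(eps: EpochSet, repetitions: int) -> EpochSet:
    """Average each stimulus code's first ``repetitions`` epochs.

    This is the averaging the speller applies before classification:
    coherent ERP signal adds up while i.i.d. noise variance shrinks by
    1/repetitions. Output holds one epoch per distinct code, ordered by
    code; a code's label is that of its contributing trials.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    out_epochs, out_codes, out_labels = [], [], []
    have_labels = eps.labels is not None
    for code in np.unique(eps.codes):
        idx = np.flatnonzero(eps.codes == code)
        if len(idx) < repetitions:
            raise ValueError(
                f"code {code} occurs {len(idx)} times, fewer than the "
                f"{repetitions} repetitions requested"
            )
        take = idx[:repetitions]
        out_epochs.append(eps.epochs[take].mean(axis=0))
        out_codes.append(code)
        if have_labels:
            out_labels.append(bool(eps.labels[take].any()))
    return EpochSet(
        np.stack(out_epochs), eps.fs_out, np.asarray(out_codes),
        np.asarray(out_labels) if have_labels else None,
    )


def _regularization_grid() -> np.ndarray:
    return 2.0 ** np.arange(-10, 11)


def calibrate(calib: EpochSet, seed: int = 0, n_folds: int = 10,
              grid: np.ndarray | None = None) -> ERPModel:
    """Train the linear target/non-target classifier on labelled epochs.

    Features are z-scored with calibration-set statistics (reapplied
    unchanged at decode time). The L2-regularized hinge-loss classifier is
    trained at each grid value of the regularization parameter; the value
    maximizing mean stratified ``n_folds``-fold CV accuracy is kept, ties
    broken toward stronger regularization. Fold assignment is fixed by
    ``seed``.
    """
    if calib.labels is None:
        raise ValueError("calibration epochs must carry target labels")
    y = calib.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("calibration data must contain both classes")
    X = calib.features()
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    Xn = (X - means) / sds

    grid = _regularization_grid() if grid is None else np.asarray(grid, dtype=float)
    n_folds = min(n_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed)
    folds = list(cv.split(Xn, y))
    best_c, best_acc = None, -1.0
    with warnings.catch_warnings():
        # weakly regularized grid points may not fully converge; they are
        # simply outscored in CV, so the warning is noise here
        warnings.simplefilter("ignore", ConvergenceWarning)
        for c in sorted(grid):  # ascending C = strongest regularization first
            accs = []
            for tr, te in folds:
                clf = LinearSVC(C=c, loss="hinge", max_iter=20000,
                                random_state=seed)
                clf.fit(Xn[tr], y[tr])
                accs.append(clf.score(Xn[te], y[te]))
            acc = float(np.mean(accs))
            if acc > best_acc:  # strict: ties stay with the smaller (stronger) C
                best_acc, best_c = acc, c
        clf = LinearSVC(C=best_c, loss="hinge", max_iter=20000, random_state=seed)
        clf.fit(Xn, y)
    return ERPModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        feature_means=means,
        feature_sds=sds,
        regularization=float(best_c),
        cv_accuracy=best_acc,
    )


def calibrate_from_session(
    rec: EEGRecording, events: list[StimulusEvent], cfg: P3SpellerConfig,
    repetitions: int | None = None, seed: int = 0,
) -> ERPModel:
    """Calibrate from a supervised spelling run (known target symbols).

    The recording is preprocessed and epoched; within each symbol
    selection the epochs of each stimulus code are averaged over
    ``repetitions`` (defaults to the config's), producing one training
    exemplar per code per selection — the same averaging level used at
    decode time.
    """
    reps = cfg.repetitions if repetitions is None else repetitions
    filtered = preprocess_p3(rec)
    eps = epoch_and_downsample(filtered, events)
    per_symbol = cfg.n_stimuli * cfg.repetitions
    if eps.n_trials % per_symbol:
        raise ValueError("event count is not a whole number of selections")
    chunks = []
    for start in range(0, eps.n_trials, per_symbol):
        sub = EpochSet(
            eps.epochs[start : start + per_symbol], eps.fs_out,
            eps.codes[start : start + per_symbol],
            eps.labels[start : start + per_symbol],
        )
        chunks.append(average_by_code(sub, reps))
    merged = EpochSet(
        np.concatenate([c.epochs for c in chunks]),
        eps.fs_out,
        np.concatenate([c.codes for c in chunks]),
        np.concatenate([c.labels for c in chunks]),
    )
    return calibrate(merged, seed=seed)


def decode_symbol(model: ERPModel, averaged: EpochSet,
                  cfg: P3SpellerConfig) -> str:
    """Select the symbol from per-code averaged epochs.

    Row/column style: the symbol at the intersection of the
    highest-scoring row (codes 0-5) and column (codes 6-11).
    Single-symbol style: the highest-scoring symbol. Ties break toward
    the lowest code index.
    """
    expected = set(range(cfg.n_stimuli))
    present = set(int(c) for c in averaged.codes)
    if present != expected:
        missing = sorted(expected - present)
        raise ValueError(f"missing averaged epochs for codes {missing}")
    order = np.argsort(averaged.codes)
    scores = model.score(averaged.features()[order])
    if cfg.style == ROW_COLUMN:
        row = int(np.argmax(scores[:6]))
        col = int(np.argmax(scores[6:12]))
        return cfg.symbol_at(row, col)
    return cfg.matrix[int(np.argmax(scores))]


def decode_session(
    model: ERPModel, rec: EEGRecording, events: list[StimulusEvent],
    cfg: P3SpellerConfig, repetitions: int | None = None,
) -> list[str]:
    """Decode a whole spelling run into its sequence of symbols.

    Events arrive chronologically, ``n_stimuli * cfg.repetitions`` per
    symbol selection. Decoding may use fewer repetitions than recorded
    (the first ``repetitions`` occurrences of each code are averaged).
    """
    reps = cfg.repetitions if repetitions is None else repetitions
    filtered = preprocess_p3(rec)
    eps = epoch_and_downsample(filtered, events)
    per_symbol = cfg.n_stimuli * cfg.repetitions
    if eps.n_trials % per_symbol:
        raise ValueError("event count is not a whole number of selections")
    out = []
    for start in range(0, eps.n_trials, per_symbol):
        sub = EpochSet(
            eps.epochs[start : start + per_symbol], eps.fs_out,
            eps.codes[start : start + per_symbol],
            None if eps.labels is None else eps.labels[start : start + per_symbol],
        )
        out.append(decode_symbol(model, average_by_code(sub, reps), cfg))
    return out
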