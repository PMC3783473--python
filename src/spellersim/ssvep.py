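"""SSVEP hierarchical-speller decoding pipeline.

The detector follows the minimum-energy-combination (MEC) approach:

1. preprocess: downsample to 250 Hz (anti-aliased), zero-phase 4 Hz
   high-pass, 50 Hz notch;
2. spatial filtering: project the sin/cos pairs of ALL candidate
   stimulation frequencies and their harmonics out of the analysis
   window, eigendecompose the residual (noise) covariance and keep the
   channel combinations with the smallest noise energy;
3. scoring: for each candidate frequency, the SNR — least-squares
   sinusoid power over locally estimated residual noise power —
   averaged across harmonics and retained components;
4. decision: the candidate with the highest score is the attended
   quadrant; three successive decisions descend the 64-symbol tree.

No calibration is required: the sinusoid models are fixed by the
stimulation frequencies alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import paradigms
from .paradigms import SSVEPSpellerConfig
from .synthetic import EEGRecording, StimulusEvent

__all__ = [
    "SpatialFilterBank",
    "FrequencyScoreSet",
    "preprocess_ssvep",
    "sinusoid_basis",
    "build_mec_filter",
    "score_frequencies",
    "decide_quadrant",
    "spell_symbol",
    "decode_session",
]

FS_TARGET = 250.0


@dataclass
class SpatialFilterBank:
    """Noise-minimizing channel combinations.

    ``weights[:, j]`` maps channels to the j-th component; components are
    ordered by ascending residual-noise energy and scaled so each has
    unit noise energy on the window it was built from.
    """

    weights: np.ndarray
    noise_energies: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Project ``[n_channels, n_samples]`` data onto the components."""
        return self.weights.T @ data


@dataclass
class FrequencyScoreSet:
    """Mean SNR per candidate frequency and the winning index."""

    frequencies: tuple[float, ...]
    scores: np.ndarray

    @property
    def argmax(self) -> int:
        # np.argmax returns the first maximum: ties break toward the
        # lowest frequency index, as documented.
        return int(np.argmax(self.scores))


def preprocess_ssvep(rec: EEGRecording, fs_target: float = FS_TARGET,
                     highpass_hz: float = 4.0, notch_hz: float = 50.0) -> EEGRecording:
    """Downsample to 250 Hz, high-pass above 4 Hz, notch out 50 Hz.

    Decimation is preceded by an 8th-order 100 Hz low-pass so no energy
    aliases into the analysis band; the high-pass is a 4th-order
    zero-phase Butterworth and the notch a zero-phase IIR notch.
    """
    data, fs = rec.data, rec.fs
    if data.shape[1] < 3 * fs_target:
        raise ValueError("recording too short for SSVEP preprocessing")
    if fs != fs_target:
        factor = fs / fs_target
        if abs(factor - round(factor)) > 1e-9:
            data = signal.resample_poly(data, int(fs_target), int(fs), axis=1)
        else:
            anti = signal.butter(8, 100.0, btype="lowpass", fs=fs, output="sos")
            data = signal.sosfiltfilt(anti, data, axis=1)[:, :: int(round(factor))]
        fs = fs_target
    hp = signal.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(hp, data, axis=1)
    b, a = signal.iirnotch(notch_hz, Q=30.0, fs=fs)
    data = signal.filtfilt(b, a, data, axis=1)
    return EEGRecording(data, fs, rec.channels)


def sinusoid_basis(frequency: float, n_harmonics: int, n_samples: int,
                   fs: float) -> np.ndarray:
    """Sin/cos regressor pairs at ``k * frequency`` for k = 1..n_harmonics.

    Harmonics at or above the Nyquist rate are dropped (with a warning);
    the phase of the stimulus oscillation is absorbed by the pair.
    """
    t = np.arange(n_samples) / fs
    cols = []
    for k in range(1, n_harmonics + 1):
        f = k * frequency
        if f >= fs / 2:
            warnings.warn(
                f"harmonic {k} of {frequency} Hz is above the Nyquist rate; skipped",
                stacklevel=2,
            )
            continue
        cols.append(np.sin(2 * np.pi * f * t))
        cols.append(np.cos(2 * np.pi * f * t))
    if not cols:
        raise ValueError(f"no harmonic of {frequency} Hz fits below Nyquist")
    return np.column_stack(cols)


def _project_out(X: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Least-squares residual of ``X`` (samples x channels) on ``basis``."""
    coef, *_ = np.linalg.lstsq(basis, X, rcond=None)
    return X - basis @ coef


def build_mec_filter(rec: EEGRecording, candidates: tuple[float, ...],
                     n_harmonics: int = 2,
                     retention: float = 0.10) -> SpatialFilterBank:
    """Minimum-energy-combination spatial filter from one analysis window.

    The sinusoid bases of all candidate frequencies are removed jointly
    (so no candidate's signal leaks into the noise estimate); the
    eigenvectors of the residual covariance with the smallest eigenvalues
    are kept while their cumulative eigenvalue share stays within
    ``retention`` of the total (at least one component), each scaled to
    unit residual-noise energy.
    """
    if rec.n_samples < rec.fs:
        raise ValueError("MEC window must cover at least 1 s")
    X = rec.data.T  # samples x channels
    basis = np.column_stack(
        [sinusoid_basis(f, n_harmonics, rec.n_samples, rec.fs) for f in candidates]
    )
    resid = _project_out(X, basis)
    cov = resid.T @ resid
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    eigvals = np.clip(eigvals, 0.0, None)
    total = eigvals.sum()
    if total <= 0:
        warnings.warn("rank-deficient noise covariance; keeping one unscaled "
                      "component", stacklevel=2)
        w = eigvecs[:, :1]
        return SpatialFilterBank(w, eigvals[:1])
    n_keep = 1
    cum = eigvals[0]
    threshold = retention * total * (1.0 + 1e-12)  # absorb summation rounding
    for j in range(1, len(eigvals)):
        if cum + eigvals[j] > threshold:
            break
        cum += eigvals[j]
        n_keep = j + 1
    kept_vals = eigvals[:n_keep]
    scales = np.where(kept_vals > 0, 1.0 / np.sqrt(np.maximum(kept_vals, 1e-30)), 1.0)
    if (kept_vals <= 0).any():
        warnings.warn("zero noise eigenvalue; pseudo-inverse scaling applied",
                      stacklevel=2)
    w = eigvecs[:, :n_keep] * scales[None, :]
    return SpatialFilterBank(w, kept_vals)


#: Probe offsets (Hz) at which the local noise level is measured.
NOISE_PROBE_OFFSETS = (-0.95, -0.75, -0.55, -0.35, 0.35, 0.55, 0.75, 0.95)


def _fit_power(x: np.ndarray, f: float, n_samples: int, fs: float) -> float:
    """Mean-square amplitude captured by an LS sin/cos fit at ``f``."""
    basis = sinusoid_basis(f, 1, n_samples, fs)
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return 0.5 * float(coef @ coef)


def _noise_power_at(resid: np.ndarray, f: float, excluded: np.ndarray,
                    fs: float) -> float:
    """Local noise level at ``f`` estimated from the projection residual.

    The noise is probed with the same least-squares sinusoid estimator
    used for the signal, at a ring of offset frequencies around ``f``
    (within about +-1 Hz), so signal and noise estimates share their
    equivalent noise bandwidth and no bias arises from how a candidate
    frequency falls on the periodogram grid. Probes landing on another
    projected-out candidate harmonic are skipped.
    """
    n = len(resid)
    powers = []
    for off in NOISE_PROBE_OFFSETS:
        fp = f + off
        if fp <= 0 or fp >= fs / 2:
            continue
        if np.any(np.abs(excluded - fp) < 0.25):
            continue
        powers.append(_fit_power(resid, fp, n, fs))
    if not powers:  # crowded neighbourhood: fall back to a wider ring
        for off in (-2.0, -1.5, 1.5, 2.0):
            fp = f + off
            if 0 < fp < fs / 2 and not np.any(np.abs(excluded - fp) < 0.25):
                powers.append(_fit_power(resid, fp, n, fs))
    return float(np.mean(powers)) if powers else float(np.mean(resid**2))


def score_frequencies(components: np.ndarray, fs: float,
                      candidates: tuple[float, ...],
                      n_harmonics: int = 2) -> FrequencyScoreSet:
    """Harmonic- and component-averaged SNR for each candidate frequency.

    For every retained component and harmonic ``k``: signal power is the
    mean-square amplitude of the least-squares sin/cos fit at ``k*f``;
    noise power is the local level of the all-candidate projection
    residual in a +-1 Hz ring around ``k*f``, measured with the same
    least-squares estimator (see :func:`_noise_power_at`). The candidate
    score is the mean of these power ratios.
    """
    S = np.atleast_2d(components)
    n_samples = S.shape[1]
    if n_samples < fs:
        raise ValueError("analysis window must cover at least 1 s")
    joint = np.column_stack(
        [sinusoid_basis(f, n_harmonics, n_samples, fs) for f in candidates]
    )
    resid = _project_out(S.T, joint).T  # components x samples
    excluded = np.array(
        [k * f for f in candidates for k in range(1, n_harmonics + 1)
         if k * f < fs / 2]
    )
    scores = np.zeros(len(candidates))
    for i, f in enumerate(candidates):
        ratios = []
        for comp, comp_resid in zip(S, resid):
            for k in range(1, n_harmonics + 1):
                fk = k * f
                if fk >= fs / 2:
                    continue
                sig_power = _fit_power(comp, fk, n_samples, fs)
                noise_power = _noise_power_at(comp_resid, fk, excluded, fs)
                if noise_power <= 0:
                    noise_power = np.finfo(float).tiny
                ratios.append(sig_power / noise_power)
        scores[i] = float(np.mean(ratios)) if ratios else 0.0
    return FrequencyScoreSet(tuple(candidates), scores)


def decide_quadrant(scores: FrequencyScoreSet) -> int:
    """Index (0-3) of the highest-scoring candidate frequency."""
    if len(scores.scores) != 4:
        raise ValueError("expected scores for exactly 4 candidate frequencies")
    return scores.argmax


def classify_window(rec: EEGRecording, cfg: SSVEPSpellerConfig,
                    n_harmonics: int = 2, retention: float = 0.10) -> int:
    """One 4-way frequency decision on a preprocessed analysis window."""
    bank = build_mec_filter(rec, cfg.frequencies, n_harmonics, retention)
    comps = bank.apply(rec.data)
    return decide_quadrant(
        score_frequencies(comps, rec.fs, cfg.frequencies, n_harmonics)
    )


def spell_symbol(segments: list[EEGRecording], cfg: SSVEPSpellerConfig,
                 n_harmonics: int = 2, retention: float = 0.10) -> str:
    """Compose three quadrant decisions into one spelled symbol."""
    if len(segments) != 3:
        raise ValueError("exactly 3 stimulation segments required per symbol")
    state: tuple[str, ...] | None = None
    result: tuple[str, ...] | str = tuple(cfg.alphabet)
    for seg in segments:
        q = classify_window(seg, cfg, n_harmonics, retention)
        result = paradigms.hierarchical_descend(cfg, state, q)
        state = result if isinstance(result, tuple) else None
    assert isinstance(result, str)
    return result


def decode_session(rec: EEGRecording, events: list[StimulusEvent],
                   cfg: SSVEPSpellerConfig, n_harmonics: int = 2,
                   retention: float = 0.10,
                   window_s: float | None = None) -> list[str]:
    """Decode a hierarchical-speller run into its sequence of symbols.

    Events mark level-segment onsets, three per symbol. ``window_s``
    optionally restricts the analysis window to the first part of each
    level (defaults to the whole level).
    """
    if len(events) % 3:
        raise ValueError("event count must be a multiple of 3 (levels/symbol)")
    pre = preprocess_ssvep(rec)
    scale = pre.fs / rec.fs
    seg_len = int(round(cfg.level_duration_s * pre.fs))
    use = seg_len if window_s is None else int(round(window_s * pre.fs))
    use = min(use, seg_len)
    out = []
    for sym_start in range(0, len(events), 3):
        segs = []
        for lvl in range(3):
            onset = int(round(events[sym_start + lvl].onset_sample * scale))
            segs.append(EEGRecording(pre.data[:, onset : onset + use], pre.fs,
                                     pre.channels))
        out.append(spell_symbol(segs, cfg, n_harmonics, retention))
    return out
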