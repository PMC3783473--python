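"""Synthetic multichannel EEG with the structure the two decoders assume.

Real patient recordings are not available, so sessions are simulated:

* oddball/ERP sessions, in which attended (target) stimuli add a positive
  P3-shaped transient 200-500 ms after onset on fronto-central/parietal
  channels;
* SSVEP trials, in which gazing at a flickering quadrant entrains
  occipitally-weighted oscillations at the stimulation frequency and its
  harmonics;
* full speller sessions composing either generator with the paradigm
  schedulers.

Background activity is 1/f ("pink") noise per channel plus an optional
50 Hz line-interference sinusoid. All randomness flows from one explicit
seed per call; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import paradigms
from .paradigms import P3SpellerConfig, SSVEPSpellerConfig

__all__ = [
    "EEGRecording",
    "StimulusEvent",
    "ERPGenConfig",
    "SSVEPGenConfig",
    "P3_CHANNELS",
    "SSVEP_CHANNELS",
    "pink_noise",
    "background_noise",
    "generate_oddball_session",
    "generate_ssvep_trial",
    "generate_p3_speller_session",
    "generate_ssvep_speller_session",
]

#: Fronto-central/parietal montage used for the ERP speller.
P3_CHANNELS: tuple[str, ...] = ("Fz", "FCz", "Cz", "CP1", "CP2", "P3", "Pz", "P4")
#: Occipital/parietal montage used for the SSVEP speller.
SSVEP_CHANNELS: tuple[str, ...] = ("P3", "Pz", "P4", "PO9", "O1", "Oz", "O2", "PO10")

#: Default spatial gain of the P3 transient over the ERP montage
#: (centro-parietal maximum, as the component topography suggests).
P3_PROFILE: tuple[float, ...] = (0.6, 0.8, 1.0, 0.85, 0.85, 0.7, 0.95, 0.7)
#: Default spatial gain of the SSVEP oscillation (occipital maximum).
SSVEP_PROFILE: tuple[float, ...] = (0.3, 0.4, 0.3, 0.7, 0.9, 1.0, 0.9, 0.7)


@dataclass
class EEGRecording:
    """A block of multichannel EEG in microvolts.

    ``data`` is ``[n_channels, n_samples]``; ``channels`` carries the
    ordered 10-20 labels of the montage.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a [n_channels, n_samples] matrix")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count must match the label list")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulation event: onset sample, stimulus code, target flag.

    The target flag is ground truth known only in simulation and during
    supervised calibration.
    """

    onset_sample: int
    code: int
    is_target: bool


@dataclass(frozen=True)
class ERPGenConfig:
    """Parameters of the simulated oddball/P3 response.

    The target-locked transient is a Gaussian bump of amplitude
    ``p3_amplitude`` microvolts (at the spatial-profile maximum) peaking
    ``p3_latency`` ms after stimulus onset with full width at half maximum
    ``p3_width`` ms, jittered trial-to-trial by a truncated Gaussian of SD
    ``latency_jitter_sd`` ms.
    """

    p3_amplitude: float = 5.0
    p3_latency: float = 350.0
    p3_width: float = 100.0
    spatial_profile: tuple[float, ...] = P3_PROFILE
    noise_sigma: float = 10.0
    noise_spatial_correlation: float = 0.6
    latency_jitter_sd: float = 20.0
    line_noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (
            self.p3_amplitude, self.p3_latency, self.p3_width,
            self.noise_sigma, self.latency_jitter_sd, self.line_noise_amplitude,
            *self.spatial_profile,
        )
        if not np.isfinite(vals).all():
            raise ValueError("non-finite value in ERP generator config")
        if self.p3_width <= 0:
            raise ValueError("p3_width must be positive")
        if self.noise_sigma < 0 or self.latency_jitter_sd < 0:
            raise ValueError("noise and jitter SDs cannot be negative")


@dataclass(frozen=True)
class SSVEPGenConfig:
    """Parameters of the simulated steady-state response.

    ``harmonic_amplitudes[k-1]`` is the microvolt amplitude of the
    oscillation at ``k * frequency`` (at the spatial-profile maximum);
    harmonic phases are drawn uniformly per trial.
    """

    frequency: float = 10.0
    harmonic_amplitudes: tuple[float, ...] = (2.0, 0.8)
    spatial_profile: tuple[float, ...] = SSVEP_PROFILE
    noise_sigma: float = 4.0
    noise_spatial_correlation: float = 0.6
    line_noise_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (
            self.frequency, self.noise_sigma, self.line_noise_amplitude,
            *self.harmonic_amplitudes, *self.spatial_profile,
        )
        if not np.isfinite(vals).all():
            raise ValueError("non-finite value in SSVEP generator config")
        if self.frequency <= 0:
            raise ValueError("stimulation frequency must be positive")
        if len(self.harmonic_amplitudes) < 1:
            raise ValueError("at least one harmonic amplitude required")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma cannot be negative")


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               sigma: float) -> np.ndarray:
    """1/f-spectrum Gaussian noise, unit-variance shaped then scaled to sigma.

    Generated by spectrally shaping white Gaussian noise with 1/sqrt(f)
    (the DC bin is zeroed), matching the broadband low-frequency-heavy
    structure of background EEG that the decoders' filters must suppress.
    """
    if sigma == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sigma * shaped / sd


def background_noise(rng: np.random.Generator, n_channels: int,
                     n_samples: int, sigma: float,
                     spatial_correlation: float = 0.6,
                     n_shared: int = 3) -> np.ndarray:
    """Spatially structured pink background noise.

    Scalp EEG background is strongly correlated across electrodes
    (volume conduction spreads each cortical source over the montage);
    the minimum-energy spatial filtering of the SSVEP decoder relies on
    exactly this structure. ``spatial_correlation`` is the fraction of
    noise variance contributed by ``n_shared`` pink sources with random
    fixed channel gains; the rest is independent pink noise per channel.
    Total per-channel variance averages ``sigma**2``.
    """
    if not 0 <= spatial_correlation <= 1:
        raise ValueError("spatial correlation must lie in [0, 1]")
    if sigma == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    indep = pink_noise(rng, n_channels, n_samples, 1.0)
    if spatial_correlation == 0:
        return sigma * indep
    sources = pink_noise(rng, n_shared, n_samples, 1.0)
    gains = rng.normal(size=(n_channels, n_shared))
    common = gains @ sources
    common /= np.sqrt((common**2).mean())
    return sigma * (np.sqrt(1 - spatial_correlation) * indep
                    + np.sqrt(spatial_correlation) * common)


def _p3_bump(cfg: ERPGenConfig, fs: float, latency_ms: float,
             n_samples: int) -> np.ndarray:
    """Gaussian target transient sampled over ``n_samples`` post-onset."""
    t_ms = np.arange(n_samples) / fs * 1000.0
    sigma_ms = cfg.p3_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return cfg.p3_amplitude * np.exp(-0.5 * ((t_ms - latency_ms) / sigma_ms) ** 2)


def _jittered_latency(cfg: ERPGenConfig, rng: np.random.Generator,
                      span_ms: float) -> float:
    """Trial latency, Gaussian-jittered but truncated inside the epoch."""
    lat = cfg.p3_latency + rng.normal(0.0, cfg.latency_jitter_sd)
    lo = 2.0 * cfg.p3_width / 2.355  # keep the bump body inside [0, span]
    return float(np.clip(lat, lo, span_ms - lo))


def _line_noise(rng: np.random.Generator, amplitude: float, n_channels: int,
                n_samples: int, fs: float) -> np.ndarray:
    if amplitude == 0:
        return np.zeros((n_channels, n_samples))
    t = np.arange(n_samples) / fs
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
    return amplitude * np.sin(2 * np.pi * 50.0 * t[None, :] + phases)


def generate_oddball_session(
    cfg: ERPGenConfig,
    n_targets: int,
    n_nontargets: int,
    stim_ms: float = 100.0,
    isi_range_ms: tuple[float, float] = (100.0, 300.0),
    fs: float = 1000.0,
    channels: tuple[str, ...] = P3_CHANNELS,
) -> tuple[EEGRecording, list[StimulusEvent]]:
    """Simulate a visual oddball run (rare targets among frequent non-targets).

    Stimulus order is randomized; each stimulus lasts ``stim_ms`` and is
    followed by a pause drawn uniformly from ``isi_range_ms``. Target
    stimuli add the P3 transient; an 800 ms tail is appended so the final
    epoch fits. Identical config and seed give bit-identical output.
    """
    if n_targets < 0 or n_nontargets < 0:
        raise ValueError("stimulus counts cannot be negative")
    if stim_ms <= 0:
        raise ValueError("stimulus duration must be positive")
    lo, hi = isi_range_ms
    if lo < 0 or hi < lo:
        raise ValueError("invalid ISI range")
    rng = np.random.default_rng(cfg.seed)
    n_stim = n_targets + n_nontargets
    flags = rng.permutation(np.r_[np.ones(n_targets, bool), np.zeros(n_nontargets, bool)])
    gaps = stim_ms + rng.uniform(lo, hi, size=n_stim)
    onsets_ms = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    onsets = np.round(onsets_ms * fs / 1000.0).astype(int)
    n_samples = (int(onsets[-1]) if n_stim else 0) + int(0.8 * fs) + int(fs)

    profile = np.asarray(cfg.spatial_profile, dtype=float)
    if len(profile) != len(channels):
        raise ValueError("spatial profile length must match the montage")
    data = background_noise(rng, len(channels), n_samples, cfg.noise_sigma,
                            cfg.noise_spatial_correlation)
    data += _line_noise(rng, cfg.line_noise_amplitude, len(channels), n_samples, fs)
    span = int(0.8 * fs)
    events = []
    for onset, flag in zip(onsets, flags):
        if flag:
            lat = _jittered_latency(cfg, rng, 800.0)
            bump = _p3_bump(cfg, fs, lat, span)
            data[:, onset : onset + span] += profile[:, None] * bump[None, :]
        events.append(StimulusEvent(int(onset), int(flag), bool(flag)))
    return EEGRecording(data, fs, tuple(channels)), events


def generate_ssvep_trial(
    cfg: SSVEPGenConfig,
    duration_s: float,
    fs: float = 1000.0,
    channels: tuple[str, ...] = SSVEP_CHANNELS,
) -> EEGRecording:
    """Simulate one steady-state stimulation trial.

    Each channel carries the spatial-profile-weighted sum of sinusoids at
    the stimulation frequency and its harmonics (random phases, fixed per
    trial), plus pink noise and a 50 Hz line component.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_h = len(cfg.harmonic_amplitudes)
    if n_h * cfg.frequency >= fs / 2:
        raise ValueError(
            f"harmonic {n_h} * {cfg.frequency} Hz is above the Nyquist rate"
        )
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(duration_s * fs))
    profile = np.asarray(cfg.spatial_profile, dtype=float)
    if len(profile) != len(channels):
        raise ValueError("spatial profile length must match the montage")
    t = np.arange(n_samples) / fs
    osc = np.zeros(n_samples)
    phases = rng.uniform(0, 2 * np.pi, size=n_h)
    for k, (amp, phi) in enumerate(zip(cfg.harmonic_amplitudes, phases), start=1):
        osc += amp * np.sin(2 * np.pi * k * cfg.frequency * t + phi)
    data = profile[:, None] * osc[None, :]
    data += background_noise(rng, len(channels), n_samples, cfg.noise_sigma,
                             cfg.noise_spatial_correlation)
    data += _line_noise(rng, cfg.line_noise_amplitude, len(channels), n_samples, fs)
    return EEGRecording(data, fs, tuple(channels))


def generate_p3_speller_session(
    erp_cfg: ERPGenConfig,
    speller_cfg: P3SpellerConfig,
    target_text: str,
    fs: float = 1000.0,
    inter_symbol_gap_s: float = 1.0,
    channels: tuple[str, ...] = P3_CHANNELS,
) -> tuple[EEGRecording, list[StimulusEvent], list[str]]:
    """Simulate a matrix-speller run spelling ``target_text``.

    For each symbol a randomized flash schedule is generated and the
    target-locked P3 transient is injected at the flagged events. Events
    are returned in chronological order, ``n_stimuli * repetitions`` per
    symbol; an empty text yields an empty session.
    """
    for sym in target_text:
        if sym not in speller_cfg.matrix:
            raise ValueError(f"target symbol {sym!r} not in the speller matrix")
    rng = np.random.default_rng(erp_cfg.seed)
    if not target_text:
        return EEGRecording(np.zeros((len(channels), 0)), fs, tuple(channels)), [], []

    onsets: list[int] = []
    flags: list[bool] = []
    codes: list[int] = []
    t0_ms = 0.0
    for sym in target_text:
        sched = paradigms.make_flash_schedule(speller_cfg, sym, rng)
        for o, c, f in zip(sched.onsets_ms, sched.codes, sched.is_target):
            onsets.append(int(round((t0_ms + o) * fs / 1000.0)))
            codes.append(int(c))
            flags.append(bool(f))
        t0_ms += sched.onsets_ms[-1] + speller_cfg.soi_ms + inter_symbol_gap_s * 1000.0

    n_samples = onsets[-1] + int(0.8 * fs) + int(fs)
    profile = np.asarray(erp_cfg.spatial_profile, dtype=float)
    data = background_noise(rng, len(channels), n_samples, erp_cfg.noise_sigma,
                            erp_cfg.noise_spatial_correlation)
    data += _line_noise(rng, erp_cfg.line_noise_amplitude, len(channels), n_samples, fs)
    span = int(0.8 * fs)
    events = []
    for onset, code, flag in zip(onsets, codes, flags):
        if flag and erp_cfg.p3_amplitude != 0:
            lat = _jittered_latency(erp_cfg, rng, 800.0)
            bump = _p3_bump(erp_cfg, fs, lat, span)
            data[:, onset : onset + span] += profile[:, None] * bump[None, :]
        events.append(StimulusEvent(onset, code, flag))
    return EEGRecording(data, fs, tuple(channels)), events, list(target_text)


def generate_ssvep_speller_session(
    gen_cfg: SSVEPGenConfig,
    speller_cfg: SSVEPSpellerConfig,
    target_text: str,
    fs: float = 1000.0,
    channels: tuple[str, ...] = SSVEP_CHANNELS,
) -> tuple[EEGRecording, list[StimulusEvent], list[str]]:
    """Simulate a hierarchical-speller run spelling ``target_text``.

    Each symbol produces three stimulation segments of
    ``level_duration_s``; in each, the user attends the quadrant on the
    path to the target symbol and the recording is entrained at that
    quadrant's frequency. One event marks each segment onset, its code
    being the attended quadrant.
    """
    for sym in target_text:
        if sym not in speller_cfg.alphabet:
            raise ValueError(f"target symbol {sym!r} not in the speller alphabet")
    rng = np.random.default_rng(gen_cfg.seed)
    if not target_text:
        return EEGRecording(np.zeros((len(channels), 0)), fs, tuple(channels)), [], []

    seg_len = int(round(speller_cfg.level_duration_s * fs))
    n_segments = 3 * len(target_text)
    n_samples = n_segments * seg_len
    profile = np.asarray(gen_cfg.spatial_profile, dtype=float)
    if len(profile) != len(channels):
        raise ValueError("spatial profile length must match the montage")
    data = background_noise(rng, len(channels), n_samples, gen_cfg.noise_sigma,
                            gen_cfg.noise_spatial_correlation)
    data += _line_noise(rng, gen_cfg.line_noise_amplitude, len(channels), n_samples, fs)

    events = []
    t_seg = np.arange(seg_len) / fs
    seg = 0
    for sym in target_text:
        path = paradigms.symbol_to_path(speller_cfg, sym)
        for quadrant in path:
            freq = speller_cfg.frequencies[quadrant]
            if len(gen_cfg.harmonic_amplitudes) * freq >= fs / 2:
                raise ValueError(f"harmonic of {freq} Hz above the Nyquist rate")
            osc = np.zeros(seg_len)
            phases = rng.uniform(0, 2 * np.pi, size=len(gen_cfg.harmonic_amplitudes))
            for k, (amp, phi) in enumerate(
                zip(gen_cfg.harmonic_amplitudes, phases), start=1
            ):
                osc += amp * np.sin(2 * np.pi * k * freq * t_seg + phi)
            start = seg * seg_len
            data[:, start : start + seg_len] += profile[:, None] * osc[None, :]
            events.append(StimulusEvent(start, int(quadrant), True))
            seg += 1
    return EEGRecording(data, fs, tuple(channels)), events, list(target_text)
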