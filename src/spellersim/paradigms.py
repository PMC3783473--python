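"""Speller paradigm geometry and stimulation timing.

Two spelling interfaces are modelled:

* a 6x6 matrix P300 speller in which either rows/columns or individual
  symbols are intensified in random order, the attended (rare) stimulus
  eliciting a P3 deflection; and
* a 64-symbol hierarchical SSVEP speller in which the alphabet is split
  over 4 flickering quadrants and a symbol is reached by three successive
  4-way frequency classifications.

The timing quantities (stimulus onset interval, intensification-sequence
duration, per-symbol stimulation time) are the ones a study protocol
reports, so they are exposed as small pure functions.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

__all__ = [
    "P3SpellerConfig",
    "SSVEPSpellerConfig",
    "StimulusSchedule",
    "DEFAULT_MATRIX",
    "DEFAULT_SSVEP_ALPHABET",
    "sequence_duration",
    "symbol_stimulation_time",
    "make_flash_schedule",
    "hierarchical_descend",
    "symbol_to_path",
    "path_to_symbol",
    "display_frequencies",
]

#: Default 6x6 alphanumeric matrix (A-Z then 0-9, row-major).
DEFAULT_MATRIX: tuple[str, ...] = tuple(string.ascii_uppercase + string.digits)

#: Default 64-symbol hierarchical alphabet (letters, lowercase, digits, '.', '_').
DEFAULT_SSVEP_ALPHABET: tuple[str, ...] = tuple(
    string.ascii_uppercase + string.ascii_lowercase + string.digits + "._"
)

ROW_COLUMN = "row_column"
SINGLE_SYMBOL = "single_symbol"


@dataclass(frozen=True)
class P3SpellerConfig:
    """Geometry and timing of the matrix speller.

    ``style`` selects row/column intensification (12 stimuli per sequence,
    codes 0-5 = rows, 6-11 = columns) or single-symbol intensification
    (36 stimuli, codes 0-35 row-major). The stimulus onset interval (SOI)
    is ``stimulus_duration_ms + isi_ms``. A pause between flashes is
    mandatory for row/column stimulation; the single-symbol style may run
    with no pause at all.
    """

    style: str = ROW_COLUMN
    stimulus_duration_ms: float = 125.0
    isi_ms: float = 125.0
    repetitions: int = 10
    matrix: tuple[str, ...] = DEFAULT_MATRIX

    def __post_init__(self) -> None:
        if self.style not in (ROW_COLUMN, SINGLE_SYMBOL):
            raise ValueError(f"unknown stimulation style: {self.style!r}")
        if len(self.matrix) != 36 or len(set(self.matrix)) != 36:
            raise ValueError("matrix must hold 36 distinct symbols")
        if self.stimulus_duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.isi_ms < 0:
            raise ValueError("inter-stimulus interval cannot be negative")
        if self.style == ROW_COLUMN and self.isi_ms == 0:
            raise ValueError(
                "row/column stimulation requires a pause between flashes (ISI > 0)"
            )
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def soi_ms(self) -> float:
        """Stimulus onset interval: flash duration plus pause."""
        return self.stimulus_duration_ms + self.isi_ms

    @property
    def n_stimuli(self) -> int:
        """Stimuli per intensification sequence (12 row/column, 36 single)."""
        return 12 if self.style == ROW_COLUMN else 36

    def symbol_at(self, row: int, col: int) -> str:
        return self.matrix[6 * row + col]

    def target_codes(self, symbol: str) -> frozenset[int]:
        """Stimulus codes flagged as target when ``symbol`` is attended."""
        idx = self.matrix.index(symbol)
        if self.style == SINGLE_SYMBOL:
            return frozenset({idx})
        return frozenset({idx // 6, 6 + idx % 6})


@dataclass(frozen=True)
class SSVEPSpellerConfig:
    """Geometry and timing of the hierarchical 4-quadrant speller.

    64 symbols are split over 4 quadrants of 16; each selection narrows
    the set by a factor 4, so exactly three successful frequency
    classifications communicate one symbol. Stimulation frequencies must
    be realizable on a 60 Hz display, i.e. equal ``60/d`` for an integer
    divisor ``d`` (to reporting precision of 2 decimals).
    """

    frequencies: tuple[float, float, float, float] = (6.67, 7.5, 8.57, 10.0)
    level_duration_s: float = 10.0
    alphabet: tuple[str, ...] = DEFAULT_SSVEP_ALPHABET
    refresh_hz: float = 60.0

    def __post_init__(self) -> None:
        if len(self.alphabet) != 64 or len(set(self.alphabet)) != 64:
            raise ValueError("alphabet must hold 64 distinct symbols")
        if len(self.frequencies) != 4 or len(set(self.frequencies)) != 4:
            raise ValueError("exactly 4 distinct stimulation frequencies required")
        for f in self.frequencies:
            if f <= 0:
                raise ValueError("stimulation frequencies must be positive")
            d = round(self.refresh_hz / f)
            if d < 1 or abs(round(self.refresh_hz / d, 2) - f) > 5e-3:
                raise ValueError(
                    f"{f} Hz is not a divisor frequency of the "
                    f"{self.refresh_hz} Hz display refresh"
                )
        if self.level_duration_s <= 0:
            raise ValueError("level duration must be positive")

    @property
    def n_levels(self) -> int:
        return 3

    @property
    def symbol_stimulation_s(self) -> float:
        """Total stimulation time for one symbol (three levels)."""
        return self.n_levels * self.level_duration_s


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulation plan: onset (ms), code, duration and target flag."""

    onsets_ms: np.ndarray
    codes: np.ndarray
    durations_ms: np.ndarray
    is_target: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.onsets_ms)
        if not (len(self.codes) == len(self.durations_ms) == len(self.is_target) == n):
            raise ValueError("schedule columns must have equal length")
        if n and (np.diff(self.onsets_ms) <= 0).any():
            raise ValueError("onsets must be strictly increasing")
        if n and (np.asarray(self.durations_ms) <= 0).any():
            raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return len(self.onsets_ms)


def sequence_duration(cfg: P3SpellerConfig) -> float:
    """Duration in seconds of one complete intensification sequence.

    Every stimulus of the paradigm flashes once, so the sequence lasts
    ``n_stimuli * SOI``: 12 stimuli for row/column, 36 for single-symbol.
    """
    return cfg.n_stimuli * cfg.soi_ms / 1000.0


def symbol_stimulation_time(cfg: P3SpellerConfig) -> float:
    """Stimulation time in seconds needed to communicate one symbol.

    The sequence duration multiplied by the number of repetitions of the
    intensification sequence used for spelling.
    """
    return sequence_duration(cfg) * cfg.repetitions


def make_flash_schedule(
    cfg: P3SpellerConfig, target_symbol: str, seed: int | np.random.Generator
) -> StimulusSchedule:
    """Randomized intensification schedule for one symbol selection.

    Each repetition flashes every stimulus code exactly once in a fresh
    random order. Onsets are spaced by the SOI. Target flags mark the
    target row and column (row/column style) or the target symbol itself
    (single-symbol style).
    """
    if target_symbol not in cfg.matrix:
        raise ValueError(f"target symbol {target_symbol!r} not in the matrix")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    targets = cfg.target_codes(target_symbol)
    codes = np.concatenate(
        [rng.permutation(cfg.n_stimuli) for _ in range(cfg.repetitions)]
    )
    n = len(codes)
    onsets = np.arange(n) * cfg.soi_ms
    durations = np.full(n, cfg.stimulus_duration_ms)
    flags = np.isin(codes, list(targets))
    return StimulusSchedule(onsets, codes, durations, flags)


def symbol_to_path(cfg: SSVEPSpellerConfig, symbol: str) -> tuple[int, int, int]:
    """The unique 3-quadrant path reaching ``symbol`` in the selection tree.

    The redistribution rule is a fixed row-major split: at every level the
    current candidate set (64, then 16, then 4 symbols) is cut into 4
    consecutive groups, one per quadrant.
    """
    idx = cfg.alphabet.index(symbol)
    return (idx // 16, (idx % 16) // 4, idx % 4)


def path_to_symbol(cfg: SSVEPSpellerConfig, path: tuple[int, int, int]) -> str:
    q1, q2, q3 = path
    for q in (q1, q2, q3):
        if not 0 <= q <= 3:
            raise ValueError(f"quadrant index {q} outside 0-3")
    return cfg.alphabet[16 * q1 + 4 * q2 + q3]


def hierarchical_descend(
    cfg: SSVEPSpellerConfig,
    state: tuple[str, ...] | None,
    chosen_quadrant: int,
) -> tuple[str, ...] | str:
    """Descend one level of the selection tree.

    ``state`` is the current candidate symbol set (``None`` means the full
    alphabet). Choosing a quadrant keeps the corresponding consecutive
    quarter of the candidates. Returns the narrowed tuple, or the terminal
    symbol once a single candidate remains.
    """
    if not 0 <= int(chosen_quadrant) <= 3:
        raise ValueError(f"quadrant index {chosen_quadrant} outside 0-3")
    pool: tuple[str, ...] = tuple(cfg.alphabet) if state is None else tuple(state)
    if len(pool) < 4 or len(pool) % 4:
        raise ValueError(f"cannot split a candidate set of {len(pool)} symbols")
    quarter = len(pool) // 4
    nxt = pool[quarter * chosen_quadrant : quarter * (chosen_quadrant + 1)]
    return nxt[0] if len(nxt) == 1 else nxt


def display_frequencies(refresh_hz: float, divisors: list[int]) -> list[float]:
    """Flicker frequencies realizable on a fixed-refresh display.

    A stable on-screen flicker must complete an integer number of refresh
    frames per cycle, so the usable frequencies are ``refresh_hz / d``.
    Values are rounded to 2 decimals for reporting.
    """
    out = []
    for d in divisors:
        if d < 1 or int(d) != d:
            raise ValueError(f"divisor must be a positive integer, got {d}")
        out.append(round(refresh_hz / d, 2))
    return out
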