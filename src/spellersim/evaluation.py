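"""Performance and usability metrics for the two spellers.

Covers the Wolpaw bitrate and information transfer rate (ITR), the
50%/70% usability classification of typing accuracy, the Raw NASA-TLX
workload score, and the cohort summary table combining per-patient
performance with questionnaire responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SessionRecord",
    "PerformanceSummary",
    "QuestionnaireRecord",
    "bitrate",
    "itr",
    "usability_class",
    "rtlx",
    "cohort_summary",
]

SYSTEMS = ("P3", "SSVEP")
TLX_SUBSCALES = ("MD", "PD", "TD", "OP", "EF", "FR")


@dataclass
class SessionRecord:
    """Per-symbol outcomes of one patient's runs with one system.

    ``rows`` is a DataFrame with columns ``decoded``, ``intended``,
    ``stim_time_s`` (stimulation time spent on that symbol) and
    ``speed_setting`` (repetitions or level duration label).
    """

    patient: str
    system: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"system must be one of {SYSTEMS}")
        required = {"decoded", "intended", "stim_time_s", "speed_setting"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"session rows missing columns {sorted(missing)}")
        if len(self.rows) and (self.rows["stim_time_s"] <= 0).any():
            raise ValueError("stimulation times must be positive")

    @property
    def n_symbols(self) -> int:
        return len(self.rows)

    @property
    def accuracy(self) -> float:
        if not len(self.rows):
            raise ValueError("empty session")
        return float((self.rows["decoded"] == self.rows["intended"]).mean())


@dataclass
class PerformanceSummary:
    """Pooled performance of one patient with one system."""

    patient: str
    system: str
    n_symbols: int
    accuracy: float
    alphabet_size: int
    total_time_s: float
    itr_bits_per_min: float


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One patient's ratings for one system.

    Six NASA-TLX subscales (0-100, higher = more workload), satisfaction
    (0-100), ACSA quality of life (-5..+5) and the two impairment scales
    (ALSFRS-R 0-48, Patterson 0-5). Out-of-range entries raise unless the
    record is constructed with ``validate=False`` via :meth:`from_row`,
    which flags them instead (transcription artifacts in source tables
    should be visible, not silently corrected).
    """

    patient: str
    system: str
    MD: float
    PD: float
    TD: float
    OP: float
    EF: float
    FR: float
    satisfaction: float | None = None
    acsa: float | None = None
    alsfrs_r: float | None = None
    patterson: float | None = None
    flags: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for name in TLX_SUBSCALES:
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"TLX subscale {name}={v} outside 0-100")

    @property
    def subscales(self) -> tuple[float, ...]:
        return tuple(getattr(self, s) for s in TLX_SUBSCALES)

    @classmethod
    def from_row(cls, row: dict) -> "QuestionnaireRecord":
        """Build from a table row, flagging out-of-range side fields."""
        flags = []
        bounds = {"satisfaction": (0, 100), "acsa": (-5, 5),
                  "alsfrs_r": (0, 48), "patterson": (0, 5)}
        clean = dict(row)
        for name, (lo, hi) in bounds.items():
            v = clean.get(name)
            if v is not None and not lo <= v <= hi:
                flags.append(f"{name}={v} outside [{lo}, {hi}]")
        if flags:
            warnings.warn(
                f"questionnaire row {row.get('patient')}/{row.get('system')}: "
                + "; ".join(flags),
                stacklevel=2,
            )
        clean["flags"] = tuple(flags)
        return cls(**clean)


def bitrate(P: float, M: int) -> float:
    """Wolpaw bitrate in bits per symbol.

    ``B = log2 M + P log2 P + (1-P) log2((1-P)/(M-1))`` with the
    convention ``0 log2 0 = 0``. The formula reaches 0 at chance
    (P = 1/M) but rises again below it — it would credit systematically
    wrong selections — so the whole below-chance region is reported as 0
    bits per symbol.
    """
    if not 0 <= P <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    if M < 2:
        raise ValueError("alphabet size must be at least 2")
    if P < 1.0 / M:
        return 0.0
    b = float(np.log2(M))
    if P > 0:
        b += P * float(np.log2(P))
    if P < 1:
        b += (1 - P) * float(np.log2((1 - P) / (M - 1)))
    return max(b, 0.0)


def itr(rows: pd.DataFrame, M: int) -> float:
    """Information transfer rate in bits per minute.

    ``ITR = B(P, M) * N / sum(t_i) * 60`` where ``N`` symbols were
    communicated in ``t_i`` seconds each and ``P`` is the fraction
    decoded correctly.
    """
    if not len(rows):
        raise ValueError("at least one communicated symbol required")
    total_s = float(rows["stim_time_s"].sum())
    if total_s <= 0:
        raise ValueError("total communication time must be positive")
    P = float((rows["decoded"] == rows["intended"]).mean())
    return bitrate(P, M) * len(rows) / total_s * 60.0


def usability_class(P: float) -> str:
    """Classify typing accuracy against the 50% / 70% usability thresholds.

    Below 50% a selection is more likely wrong than right (not usable);
    70% or more is the accepted threshold for a usable assistive speller;
    in between is marginal.
    """
    if not 0 <= P <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    if P < 0.5:
        return "not_usable"
    if P >= 0.7:
        return "usable"
    return "marginal"


def rtlx(q: QuestionnaireRecord) -> float:
    """Raw NASA-TLX workload: the unweighted mean of the six subscales."""
    return round(float(np.mean(q.subscales)), 2)


def summarize_sessions(record: SessionRecord, M: int) -> PerformanceSummary:
    """Pool all symbols of one patient x system into one summary.

    The patient's "global" ITR pools every symbol and its stimulation
    time across sessions and speed settings of that system.
    """
    return PerformanceSummary(
        patient=record.patient,
        system=record.system,
        n_symbols=record.n_symbols,
        accuracy=record.accuracy,
        alphabet_size=M,
        total_time_s=float(record.rows["stim_time_s"].sum()),
        itr_bits_per_min=itr(record.rows, M),
    )


def accuracy_by_speed(record: SessionRecord, min_support: int = 3) -> pd.DataFrame:
    """Accuracy per speed setting, flagging low-support points."""
    grp = record.rows.groupby("speed_setting")
    out = grp.apply(
        lambda g: pd.Series({
            "n_symbols": len(g),
            "accuracy": float((g["decoded"] == g["intended"]).mean()),
            "stim_time_s": float(g["stim_time_s"].mean()),
        }),
        include_groups=False,
    ).reset_index()
    out["low_support"] = out["n_symbols"] < min_support
    return out


def cohort_summary(
    sessions: list[SessionRecord],
    questionnaires: list[QuestionnaireRecord],
    alphabet_sizes: dict[str, int] | None = None,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-patient x system summary table with cohort averages.

    One row per patient and system (ITR, accuracy, TLX subscales, RTLX,
    satisfaction, quality of life) plus one ``mean`` row per system.
    Excluded patients (e.g. one who could not complete equal sessions
    with both systems) keep their per-patient rows but are left out of
    the averages.
    """
    sizes = alphabet_sizes or {"P3": 36, "SSVEP": 64}
    known = {s.patient for s in sessions} | {q.patient for q in questionnaires}
    for pid in exclude:
        if pid not in known:
            warnings.warn(f"excluded patient {pid!r} not present in the data",
                          stacklevel=2)
    qlook = {(q.patient, q.system): q for q in questionnaires}
    rows = []
    for s in sessions:
        perf = summarize_sessions(s, sizes[s.system])
        row = {
            "patient": s.patient, "system": s.system,
            "n_symbols": perf.n_symbols, "accuracy": perf.accuracy,
            "ITR": perf.itr_bits_per_min,
            "usability": usability_class(perf.accuracy),
        }
        q = qlook.get((s.patient, s.system))
        if q is not None:
            row.update(dict(zip(TLX_SUBSCALES, q.subscales)))
            row["RTLX"] = rtlx(q)
            row["SA"] = q.satisfaction
            row["QoL"] = q.acsa
        rows.append(row)
    table = pd.DataFrame(rows)
    if not len(table):
        return table
    numeric = table.select_dtypes("number").columns
    means = []
    for system, grp in table[~table["patient"].isin(exclude)].groupby("system"):
        m = {"patient": "mean", "system": system}
        m.update({c: float(grp[c].mean()) for c in numeric})
        means.append(m)
    return pd.concat([table, pd.DataFrame(means)], ignore_index=True)
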