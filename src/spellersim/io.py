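"""On-disk formats for sessions, decode reports and questionnaires.

A session is persisted as a pair of files plus a header:

* ``<stem>.signal.npy`` — float32 array ``[n_channels, n_samples]`` in
  microvolts (numpy ``.npy`` format);
* ``<stem>.header.json`` — ``{"fs": <Hz>, "channels": [...]}``;
* ``<stem>.events.tsv`` — tab-separated, columns ``onset_sample``
  (integer), ``code`` (integer), ``is_target`` (0/1), one row per
  stimulus, chronological order.

Decode reports and questionnaire tables are tab-separated text with
documented column sets, so the evaluation stage can consume logs from
real or simulated runs interchangeably.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import QuestionnaireRecord, SessionRecord
from .synthetic import EEGRecording, StimulusEvent

__all__ = [
    "save_session",
    "load_session",
    "save_decode_report",
    "load_decode_report",
    "load_questionnaires",
]

DECODE_REPORT_COLUMNS = ("decoded", "intended", "stim_time_s", "speed_setting")


def save_session(stem: str | Path, rec: EEGRecording,
                 events: list[StimulusEvent]) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".signal.npy"), rec.data.astype(np.float32))
    stem.with_suffix(".header.json").write_text(
        json.dumps({"fs": rec.fs, "channels": list(rec.channels)})
    )
    df = pd.DataFrame({
        "onset_sample": [e.onset_sample for e in events],
        "code": [e.code for e in events],
        "is_target": [int(e.is_target) for e in events],
    })
    df.to_csv(stem.with_suffix(".events.tsv"), sep="\t", index=False)


def load_session(stem: str | Path) -> tuple[EEGRecording, list[StimulusEvent]]:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".header.json").read_text())
    data = np.load(stem.with_suffix(".signal.npy")).astype(float)
    rec = EEGRecording(data, float(header["fs"]), tuple(header["channels"]))
    df = pd.read_csv(stem.with_suffix(".events.tsv"), sep="\t")
    events = [
        StimulusEvent(int(r.onset_sample), int(r.code), bool(r.is_target))
        for r in df.itertuples()
    ]
    return rec, events


def save_decode_report(path: str | Path, record: SessionRecord) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = record.rows[list(DECODE_REPORT_COLUMNS)].copy()
    out.insert(0, "patient", record.patient)
    out.insert(1, "system", record.system)
    out.to_csv(path, sep="\t", index=False)


def load_decode_report(path: str | Path) -> SessionRecord:
    df = pd.read_csv(path, sep="\t")
    patients = df["patient"].unique()
    systems = df["system"].unique()
    if len(patients) != 1 or len(systems) != 1:
        raise ValueError("a decode report holds one patient and one system")
    return SessionRecord(str(patients[0]), str(systems[0]),
                         df[list(DECODE_REPORT_COLUMNS)].reset_index(drop=True))


def load_questionnaires(path: str | Path) -> list[QuestionnaireRecord]:
    """Read a questionnaire table (TSV, one row per patient x system).

    Columns: patient, system, MD, PD, TD, OP, EF, FR, satisfaction, acsa,
    alsfrs_r, patterson (the last four optional). Range violations in the
    side fields are flagged with a warning, mirroring how transcription
    artifacts in published tables should surface.
    """
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        d = {k: row[k] for k in ("patient", "system", *
                                 ("MD", "PD", "TD", "OP", "EF", "FR"))}
        for opt in ("satisfaction", "acsa", "alsfrs_r", "patterson"):
            if opt in df.columns and pd.notna(row[opt]):
                d[opt] = float(row[opt])
        records.append(QuestionnaireRecord.from_row(d))
    return records
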