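"""Evaluate the simulated cohort: summary table with workload ratings.

Real questionnaire responses cannot be simulated from EEG, so a
*synthetic* questionnaire table is generated alongside the decoding
results: each virtual patient's workload ratings are drawn around a mean
that decreases with their typing accuracy (struggling users report more
effort and frustration), satisfaction increases with accuracy, and the
impairment/quality-of-life covariates are fixed per patient. The table
is written with a ``synthetic_`` prefix to keep its provenance explicit.

Reads results/cohort/ (from 02_run_cohort.py); writes
results/synthetic_questionnaires.tsv and results/cohort_summary.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from spellersim import io
from spellersim.evaluation import cohort_summary

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = ROOT / "cohort"
SEED = 77

# per-virtual-patient covariates (fixed traits of the simulated cohort):
# motor-impairment score (0-48 scale, higher = less impaired) and
# quality-of-life self-assessment (-5..+5)
COVARIATES = {
    "V1": (20, -2), "V2": (18, 3.5), "V3": (22, 3), "V4": (24, 2),
    "V5": (30, -0.8), "V6": (14, 2), "V7": (17, 0),
}


def synthesize_questionnaires(metrics: dict, seed: int = SEED) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for pid, systems in sorted(metrics["per_patient"].items()):
        for system, s in sorted(systems.items()):
            base = 75.0 - 50.0 * s["accuracy"]  # workload falls with success
            subs = np.clip(rng.normal(base, 12.0, size=6), 0, 100)
            alsfrs, qol = COVARIATES[pid]
            rows.append({
                "patient": pid, "system": system,
                "MD": round(subs[0]), "PD": round(subs[1] * 0.3),
                "TD": round(subs[2]), "OP": round(subs[3]),
                "EF": round(subs[4]), "FR": round(subs[5]),
                "satisfaction": round(float(np.clip(
                    rng.normal(30 + 60 * s["accuracy"], 8), 0, 100))),
                "acsa": qol, "alsfrs_r": alsfrs,
            })
    return pd.DataFrame(rows)


def main() -> None:
    metrics = json.loads((COHORT / "metrics.json").read_text())
    qtable = synthesize_questionnaires(metrics)
    qpath = ROOT / "synthetic_questionnaires.tsv"
    qtable.to_csv(qpath, sep="\t", index=False)

    sessions = [io.load_decode_report(p)
                for p in sorted(COHORT.glob("*/*/decode_report.tsv"))]
    questionnaires = io.load_questionnaires(qpath)
    table = cohort_summary(sessions, questionnaires)
    table.to_csv(ROOT / "cohort_summary.tsv", sep="\t", index=False,
                 float_format="%.3f")

    cols = ["patient", "system", "accuracy", "ITR", "usability", "RTLX",
            "SA", "QoL"]
    print("Cohort summary (per virtual patient and system):")
    print(table[cols].to_string(index=False))
    print(f"\nWritten to {ROOT / 'cohort_summary.tsv'}")


if __name__ == "__main__":
    main()
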