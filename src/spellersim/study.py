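"""End-to-end study workflow on a simulated cohort.

Reproduces the shape of a two-system spelling study: every virtual
patient runs acquisition sessions with both the P3 matrix speller and
the SSVEP hierarchical speller, freely spelling words while the speed
setting (repetitions / level duration) adapts to their success, exactly
as a patient would ask for faster or slower settings. Decode reports
feed the evaluation metrics and the paired Wilcoxon comparison of
per-patient ITRs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, io, p3, paradigms, ssvep, synthetic
from .evaluation import SessionRecord
from .paradigms import P3SpellerConfig, SSVEPSpellerConfig
from .stats import PairedSample, wilcoxon_signed_rank
from .synthetic import ERPGenConfig, SSVEPGenConfig

__all__ = ["PatientSpec", "CohortSpec", "run_study"]

logger = logging.getLogger(__name__)

#: Small packaged word list for free-spelling simulation (uppercase,
#: drawn from the default matrix alphabet).
WORDS = ("HELLO", "WATER", "MUSIC", "THANKS", "YES", "NO", "GOOD", "SLEEP",
         "PAIN", "HOME", "BOOK", "LIGHT")

P3_REPETITION_LADDER = (10, 8, 6, 4, 3, 2, 1)
SSVEP_DURATION_LADDER = (10.0, 7.0, 5.0, 4.0, 3.0, 2.0)


@dataclass
class PatientSpec:
    """Generator and paradigm settings of one virtual patient."""

    patient_id: str
    erp_cfg: ERPGenConfig = field(default_factory=ERPGenConfig)
    ssvep_cfg: SSVEPGenConfig = field(default_factory=SSVEPGenConfig)
    p3_speller: P3SpellerConfig = field(default_factory=P3SpellerConfig)
    ssvep_speller: SSVEPSpellerConfig = field(default_factory=SSVEPSpellerConfig)
    words_per_session: int = 2
    sessions_per_system: int = 2


@dataclass
class CohortSpec:
    """The whole simulated cohort plus the master seed."""

    patients: list[PatientSpec]
    seed: int = 0
    calib_symbols: int = 8
    save_signals: bool = False

    def __post_init__(self) -> None:
        if not self.patients:
            raise ValueError("at least one patient required")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be distinct")


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % 2**31)


def _step_setting(idx: int, accuracy: float, ladder_len: int) -> int:
    """Speed-adaptation policy.

    After a fully correct word, step to the next faster setting; after a
    word with at least 50% errors, step back to a slower one; otherwise
    keep the current setting.
    """
    if accuracy == 1.0:
        return min(idx + 1, ladder_len - 1)
    if accuracy <= 0.5:
        return max(idx - 1, 0)
    return idx


def _pick_words(rng: np.random.Generator, n: int) -> list[str]:
    return [WORDS[i] for i in rng.integers(0, len(WORDS), size=n)]


def _run_p3_sessions(pat: PatientSpec, master_seed: int, p_idx: int,
                     out_dir: Path | None, save_signals: bool,
                     calib_symbols: int) -> SessionRecord:
    rows = []
    for ses in range(pat.sessions_per_system):
        seed = _derived_seed(master_seed, p_idx, 0, ses)
        rng = np.random.default_rng(seed)
        # supervised calibration run: known random symbols, full repetitions
        calib_text = "".join(
            pat.p3_speller.matrix[i]
            for i in rng.integers(0, 36, size=calib_symbols)
        )
        erp = dataclasses.replace(pat.erp_cfg, seed=_derived_seed(seed, 1))
        rec, events, _ = synthetic.generate_p3_speller_session(
            erp, pat.p3_speller, calib_text
        )
        model = p3.calibrate_from_session(rec, events, pat.p3_speller,
                                          seed=_derived_seed(seed, 2))
        setting = 0
        for w_idx in range(pat.words_per_session):
            word = _pick_words(rng, 1)[0]
            reps = P3_REPETITION_LADDER[setting]
            cfg = dataclasses.replace(pat.p3_speller, repetitions=reps)
            erp_w = dataclasses.replace(pat.erp_cfg,
                                        seed=_derived_seed(seed, 3, w_idx))
            rec, events, truth = synthetic.generate_p3_speller_session(
                erp_w, cfg, word
            )
            decoded = p3.decode_session(model, rec, events, cfg)
            stim_time = paradigms.symbol_stimulation_time(cfg)
            for dec, tru in zip(decoded, truth):
                rows.append({"decoded": dec, "intended": tru,
                             "stim_time_s": stim_time,
                             "speed_setting": f"reps={reps}"})
            acc = float(np.mean([d == t for d, t in zip(decoded, truth)]))
            setting = _step_setting(setting, acc, len(P3_REPETITION_LADDER))
            if out_dir is not None and save_signals:
                io.save_session(out_dir / f"session{ses}_word{w_idx}",
                                rec, events)
    record = SessionRecord(pat.patient_id, "P3", pd.DataFrame(rows))
    if out_dir is not None:
        io.save_decode_report(out_dir / "decode_report.tsv", record)
    return record


def _run_ssvep_sessions(pat: PatientSpec, master_seed: int, p_idx: int,
                        out_dir: Path | None,
                        save_signals: bool) -> SessionRecord:
    rows = []
    for ses in range(pat.sessions_per_system):
        seed = _derived_seed(master_seed, p_idx, 1, ses)
        rng = np.random.default_rng(seed)
        setting = 0
        for w_idx in range(pat.words_per_session):
            word = _pick_words(rng, 1)[0]
            dur = SSVEP_DURATION_LADDER[setting]
            cfg = dataclasses.replace(pat.ssvep_speller, level_duration_s=dur)
            gen = dataclasses.replace(pat.ssvep_cfg,
                                      seed=_derived_seed(seed, 3, w_idx))
            rec, events, truth = synthetic.generate_ssvep_speller_session(
                gen, cfg, word
            )
            decoded = ssvep.decode_session(rec, events, cfg)
            for dec, tru in zip(decoded, truth):
                rows.append({"decoded": dec, "intended": tru,
                             "stim_time_s": cfg.symbol_stimulation_s,
                             "speed_setting": f"level={dur:g}s"})
            acc = float(np.mean([d == t for d, t in zip(decoded, truth)]))
            setting = _step_setting(setting, acc, len(SSVEP_DURATION_LADDER))
            if out_dir is not None and save_signals:
                io.save_session(out_dir / f"session{ses}_word{w_idx}",
                                rec, events)
    record = SessionRecord(pat.patient_id, "SSVEP", pd.DataFrame(rows))
    if out_dir is not None:
        io.save_decode_report(out_dir / "decode_report.tsv", record)
    return record


def run_study(spec: CohortSpec, out_dir: str | Path | None = None) -> dict:
    """Simulate, decode, evaluate and compare both systems on a cohort.

    Returns (and writes, when ``out_dir`` is given) a metrics bundle:
    per-patient performance summaries for both systems, the cohort
    summary table, and the Wilcoxon signed-rank comparison of the
    per-patient global ITRs. A failing patient run is logged and skipped;
    the rest of the cohort completes.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    records: list[SessionRecord] = []
    failures: dict[str, str] = {}
    for p_idx, pat in enumerate(spec.patients):
        for system, runner in (("P3", _run_p3_sessions),
                               ("SSVEP", _run_ssvep_sessions)):
            pdir = out / pat.patient_id / system if out is not None else None
            if pdir is not None:
                pdir.mkdir(parents=True, exist_ok=True)
            try:
                if system == "P3":
                    rec = runner(pat, spec.seed, p_idx, pdir,
                                 spec.save_signals, spec.calib_symbols)
                else:
                    rec = runner(pat, spec.seed, p_idx, pdir,
                                 spec.save_signals)
                records.append(rec)
            except Exception as exc:  # partial failure: log, keep going
                logger.exception("run failed for %s/%s", pat.patient_id, system)
                failures[f"{pat.patient_id}/{system}"] = str(exc)

    summaries = {}
    for r in records:
        M = 36 if r.system == "P3" else 64
        s = evaluation.summarize_sessions(r, M)
        summaries.setdefault(r.patient, {})[r.system] = {
            "n_symbols": s.n_symbols,
            "accuracy": round(s.accuracy, 6),
            "total_time_s": round(s.total_time_s, 6),
            "itr_bits_per_min": round(s.itr_bits_per_min, 6),
            "usability": evaluation.usability_class(s.accuracy),
        }
    paired = [
        (pid, d["P3"]["itr_bits_per_min"], d["SSVEP"]["itr_bits_per_min"])
        for pid, d in sorted(summaries.items())
        if "P3" in d and "SSVEP" in d
    ]
    comparison = None
    if len(paired) >= 2:
        ids, itr_p3, itr_ssvep = zip(*paired)
        res = wilcoxon_signed_rank(
            PairedSample(np.array(itr_p3), np.array(itr_ssvep), ids)
        )
        comparison = {
            "test": "wilcoxon_signed_rank",
            "statistic_W": res.statistic,
            "p_value": res.p_value,
            "n": res.n_used,
            "method": res.method,
            "mean_itr_p3": float(np.mean(itr_p3)),
            "mean_itr_ssvep": float(np.mean(itr_ssvep)),
        }
    bundle = {
        "seed": spec.seed,
        "n_patients": len(spec.patients),
        "resolved_config": {
            "calib_symbols": spec.calib_symbols,
            "p3_repetition_ladder": list(P3_REPETITION_LADDER),
            "ssvep_duration_ladder": list(SSVEP_DURATION_LADDER),
            "patients": [
                {
                    "id": p.patient_id,
                    "words_per_session": p.words_per_session,
                    "sessions_per_system": p.sessions_per_system,
                    "p3_amplitude_uV": p.erp_cfg.p3_amplitude,
                    "p3_noise_sigma_uV": p.erp_cfg.noise_sigma,
                    "ssvep_harmonic_amplitudes_uV": list(
                        p.ssvep_cfg.harmonic_amplitudes),
                    "ssvep_noise_sigma_uV": p.ssvep_cfg.noise_sigma,
                }
                for p in spec.patients
            ],
        },
        "per_patient": summaries,
        "itr_comparison": comparison,
        "failures": failures,
    }
    if out is not None:
        (out / "metrics.json").write_text(json.dumps(bundle, indent=2,
                                                     sort_keys=True))
        manifest = {
            "layout": "one directory per patient/system with decode_report.tsv",
            "patients": sorted({r.patient for r in records}),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return bundle
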