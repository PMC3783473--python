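"""Compare the two systems and probe performance correlates.

Paired Wilcoxon signed-rank tests on the per-patient global ITR,
workload (RTLX) and satisfaction; Spearman correlation (with a
20000-permutation significance test) between each system's ITR and the
motor-impairment covariate, and the partial correlation of the pooled
ITR with impairment controlling for the system.

Reads results/cohort_summary.tsv; writes results/statistics.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from spellersim.stats import (
    PairedSample,
    spearman_partial_perm,
    spearman_perm,
    wilcoxon_signed_rank,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 909
N_PERM = 20000


def paired(table: pd.DataFrame, column: str) -> PairedSample:
    wide = table.pivot(index="patient", columns="system", values=column)
    return PairedSample(wide["P3"].to_numpy(), wide["SSVEP"].to_numpy(),
                        tuple(wide.index))


def main() -> None:
    table = pd.read_csv(ROOT / "cohort_summary.tsv", sep="\t")
    table = table[table["patient"] != "mean"]
    covars = pd.read_csv(ROOT / "synthetic_questionnaires.tsv", sep="\t")
    table = table.merge(covars[["patient", "system", "alsfrs_r"]],
                        on=["patient", "system"])

    report: dict = {"paired_tests": {}, "correlations": {}}
    for col in ("ITR", "RTLX", "SA"):
        res = wilcoxon_signed_rank(paired(table, col))
        report["paired_tests"][col] = {
            "W": res.statistic, "p": res.p_value, "n": res.n_used,
            "method": res.method,
        }
        print(f"{col}: P3 vs SSVEP Wilcoxon W={res.statistic:g}, "
              f"p={res.p_value:.4f} (n={res.n_used}, {res.method})")

    for i, system in enumerate(("P3", "SSVEP")):
        sub = table[table["system"] == system]
        res = spearman_perm(sub["alsfrs_r"], sub["ITR"], n_perm=N_PERM,
                            seed=SEED + i)
        report["correlations"][f"itr_vs_impairment_{system}"] = {
            "rho": res.coefficient, "p": res.p_value,
            "n_perm": res.n_permutations,
        }
        print(f"{system}: Spearman rho(ITR, impairment score) = "
              f"{res.coefficient:.3f}, permutation p = {res.p_value:.4f}")

    system_code = (table["system"] == "SSVEP").astype(float)
    res = spearman_partial_perm(table["alsfrs_r"], table["ITR"], system_code,
                                n_perm=N_PERM, seed=SEED + 7)
    report["correlations"]["itr_vs_impairment_partial"] = {
        "rho": res.coefficient, "p": res.p_value, "n_perm": res.n_permutations,
    }
    print(f"Pooled: partial Spearman rho(ITR, impairment | system) = "
          f"{res.coefficient:.3f}, permutation p = {res.p_value:.4f}")

    (ROOT / "statistics.json").write_text(json.dumps(report, indent=2,
                                                     sort_keys=True))
    print(f"\nWritten to {ROOT / 'statistics.json'}")


if __name__ == "__main__":
    main()
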