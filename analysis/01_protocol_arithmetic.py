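"""Protocol timing arithmetic for both spellers.

Reproduces the per-patient stimulation-parameter bookkeeping: for each
P3 configuration used in the study protocol, the duration of one
intensification sequence and the per-symbol stimulation time at 10
repetitions; for the SSVEP speller, the per-symbol stimulation time and
the flicker frequencies realizable on a 60 Hz display.

Writes results/protocol_timing.tsv and results/display_frequencies.tsv.
"""

from pathlib import Path

import pandas as pd

from spellersim.paradigms import (
    P3SpellerConfig,
    SSVEPSpellerConfig,
    display_frequencies,
    sequence_duration,
    symbol_stimulation_time,
)

OUT = Path(__file__).resolve().parents[1] / "results"

# stimulation style and timing chosen per patient during their
# preliminary session
P3_PROTOCOL = [
    ("S1", "single_symbol", 100, 0),
    ("S2", "single_symbol", 100, 0),
    ("S3", "row_column", 100, 150),
    ("S4", "row_column", 125, 125),
    ("S5", "row_column", 125, 125),
    ("S6", "single_symbol", 100, 50),
    ("S7", "row_column", 125, 125),
]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for pid, style, stim, isi in P3_PROTOCOL:
        cfg = P3SpellerConfig(style=style, stimulus_duration_ms=stim,
                              isi_ms=isi, repetitions=10)
        rows.append({
            "patient": pid,
            "style": style,
            "stimulus_ms": stim,
            "isi_ms": isi,
            "soi_ms": cfg.soi_ms,
            "sequence_s": sequence_duration(cfg),
            "symbol_time_10reps_s": symbol_stimulation_time(cfg),
        })
    timing = pd.DataFrame(rows)
    timing.to_csv(OUT / "protocol_timing.tsv", sep="\t", index=False)

    ssvep = SSVEPSpellerConfig(level_duration_s=10.0)
    freqs = pd.DataFrame({
        "divisor_of_60Hz": [3, 4, 5, 6, 7, 8, 9, 10],
        "frequency_hz": display_frequencies(60, [3, 4, 5, 6, 7, 8, 9, 10]),
    })
    freqs.to_csv(OUT / "display_frequencies.tsv", sep="\t", index=False)

    print("One intensification sequence (s) per protocol row:")
    print(timing.to_string(index=False))
    print(f"\nSSVEP: {ssvep.symbol_stimulation_s:g} s of stimulation per "
          f"symbol at {ssvep.level_duration_s:g} s per level "
          f"(3 levels, 64 symbols).")
    print("\nDisplay-locked flicker frequencies (60 Hz refresh):")
    print(freqs.to_string(index=False))


if __name__ == "__main__":
    main()
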