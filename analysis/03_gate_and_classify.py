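"""Gate each cohort, classify every event, and measure gate purity.

Applies the hierarchical gate tree (multiplets by brightfield area, then
the CD71 x macrophage-marker double-positive "EBI gate"; the macrophage
axis is F4/80 for mouse tissues and CD163 for rat), then runs the
rule-based classifier on every event and reports how much of the
double-positive gate is genuine islands.

Run from the repository root:  python analysis/03_gate_and_classify.py
"""

from pathlib import Path

import pandas as pd

from ebiflow import (ClassifyConfig, apply_gates, classify_cohort,
                     default_ebi_gates, read_object_dir)
from ebiflow.io import write_table
from ebiflow.stats import gate_purity

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

PRESETS = ("BM", "FL", "SP_stress", "ratBM")


def main() -> None:
    purity_rows = []
    for preset in PRESETS:
        species = "rat" if preset == "ratBM" else "mouse"
        feats = pd.read_csv(RESULTS / f"features_{preset}.csv")
        truth = pd.read_csv(RESULTS / f"truth_{preset}.csv")
        gates = default_ebi_gates(species=species, features=feats, truth=truth)
        pops = apply_gates(feats, gates)
        write_table(pops.membership.reset_index(),
                    RESULTS / f"gates_{preset}.csv")

        calls = classify_cohort(read_object_dir(COHORT_DIR / preset),
                                ClassifyConfig(species=species))
        write_table(calls, RESULTS / f"calls_{preset}.csv")

        purity = gate_purity(calls, pops.members("ebi_gate"))
        purity_rows.append({"preset": preset, **purity})
        print(f"[{preset}] multiplets {pops.counts['multiplets']}, "
              f"EBI gate {pops.counts['ebi_gate']}; "
              f"purity {purity['p_hat']:.2f} "
              f"({purity['k']}/{purity['n']} called EBI)")
        print(calls["call"].value_counts().sort_index()
              .to_string().replace("\n", "\n    "))
    write_table(pd.DataFrame(purity_rows).rename(columns={"p_hat": "purity"}),
                RESULTS / "gate_purity.csv")


if __name__ == "__main__":
    main()
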