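"""Cohort statistics: recovery vs truth, shape contrast, marker phenotypes.

Joins each cohort's calls with its ground truth and reports:

* class-call accuracy and island recall per preset;
* the fetal-liver vs bone-marrow circularity contrast on called EBI
  macrophages (Wilcoxon rank-sum, two-tailed);
* Similarity of VCAM-1 / CD169 / CD11b to F4/80 on mouse BM islands —
  continuous co-expression should rank above patchy above disjoint;
* CD11b accounting: the central macrophage is expected CD11b-negative while
  most BM islands carry at least one CD11b+ satellite.

Run from the repository root:  python analysis/04_cohort_statistics.py
"""

from pathlib import Path

import pandas as pd

from ebiflow import summarize_groups, wilcoxon_rank_sum
from ebiflow.io import write_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

PRESETS = ("BM", "FL", "SP_stress", "ratBM")
SINGLETS = {"singlet_erythroblast", "singlet_myeloid", "singlet_macrophage"}


def load(preset: str) -> pd.DataFrame:
    calls = pd.read_csv(RESULTS / f"calls_{preset}.csv")
    truth = pd.read_csv(RESULTS / f"truth_{preset}.csv")
    m = calls.merge(truth, on="object_id", suffixes=("", "_true"))
    m["truth_call"] = m["true_class"].map(
        lambda c: "singlet" if c in SINGLETS else c)
    m["preset"] = preset
    return m


def main() -> None:
    merged = {p: load(p) for p in PRESETS}

    print("== recovery vs planted truth ==")
    for preset, m in merged.items():
        acc = (m["call"] == m["truth_call"]).mean()
        ebi = m[m["true_class"] == "EBI"]
        recall = (ebi["call"] == "EBI").mean()
        print(f"[{preset}] accuracy {acc:.3f}, island recall {recall:.3f} "
              f"({len(ebi)} planted islands)")

    print("\n== macrophage shape: fetal liver vs bone marrow ==")
    circ = {}
    for preset in ("FL", "BM"):
        c = merged[preset]
        circ[preset] = c.loc[c["call"] == "EBI",
                             "central_circularity"].dropna()
        print(f"[{preset}] median circularity "
              f"{circ[preset].median():.2f} (n={len(circ[preset])})")
    _, p = wilcoxon_rank_sum(circ["FL"], circ["BM"])
    print(f"Wilcoxon two-tailed p = {p:.2e} "
          f"({'FL rounder' if circ['FL'].median() > circ['BM'].median() else 'BM rounder'})")

    print("\n== marker phenotype of called BM island macrophages ==")
    bm = merged["BM"]
    ebis = bm[bm["call"] == "EBI"]
    for ch in ("VCAM1", "CD169", "CD11b"):
        s = ebis[f"similarity_{ch}"].dropna()
        print(f"similarity {ch} vs F4/80: mean {s.mean():.2f} "
              f"+/- {s.std(ddof=1):.2f} (n={len(s)})")
    cd169_pos = (ebis["central_CD169"] == "positive").mean()
    central_neg = (ebis["central_cd11b_positive"] == False).mean()  # noqa: E712
    with_sat = (ebis["n_cd11b_cells"].astype(float) >= 1).mean()
    print(f"central macrophage CD169+ by mean pixel: {100 * cd169_pos:.1f}%")
    print(f"central macrophage CD11b-negative: {100 * central_neg:.1f}%")
    print(f"islands with >=1 CD11b+ satellite: {100 * with_sat:.1f}%")

    all_calls = pd.concat(merged.values(), ignore_index=True)
    summary = summarize_groups(
        all_calls[all_calls["call"] == "EBI"], "preset",
        ["central_circularity", "n_erythroblasts", "n_cd11b_cells"])
    write_table(summary, RESULTS / "ebi_summary_by_preset.csv")
    print(f"\nwrote {RESULTS / 'ebi_summary_by_preset.csv'}")


if __name__ == "__main__":
    main()
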