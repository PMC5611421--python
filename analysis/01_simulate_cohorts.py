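"""Simulate one seeded cohort per tissue preset and write them to disk.

Generates mouse bone marrow (BM), E13.5 fetal liver (FL), post-phlebotomy
spleen (SP_stress) and rat bone marrow (ratBM) cohorts of per-event
multichannel TIFF frames with ground-truth tables.  Image stacks are bulky,
so they go under scratch/; the truth tables are copied to results/.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

from pathlib import Path

from ebiflow import preset_config, simulate_cohort, write_cohort
from ebiflow.io import write_table

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

PRESETS = ("BM", "FL", "SP_stress", "ratBM")
N_OBJECTS = 150
BASE_SEED = 20260


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for i, preset in enumerate(PRESETS):
        cfg = preset_config(preset, n_objects=N_OBJECTS, seed=BASE_SEED + i)
        images, truth = simulate_cohort(cfg)
        outdir = write_cohort(images, truth, COHORT_DIR / preset)
        cols = [c for c in truth.columns if c != "macrophage_mask"]
        write_table(truth[cols], RESULTS / f"truth_{preset}.csv")
        tally = truth["true_class"].value_counts().sort_index()
        print(f"[{preset}] {len(images)} objects -> {outdir}")
        for cls, n in tally.items():
            print(f"    {cls:<28s}{n}")


if __name__ == "__main__":
    main()
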