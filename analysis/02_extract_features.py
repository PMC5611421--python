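"""Compute the per-object feature table for every simulated cohort.

Reads the TIFF cohorts written by 01_simulate_cohorts.py and computes, per
event: brightfield area (px and um^2), background-subtracted integrated
intensity and mean pixel per marker, object-mask circularity, and the
Similarity of VCAM-1, CD169 and CD11b against F4/80 over the object mask.

Run from the repository root:  python analysis/02_extract_features.py
"""

from pathlib import Path

from ebiflow import compute_feature_table, read_object_dir
from ebiflow.io import write_table

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

PRESETS = ("BM", "FL", "SP_stress", "ratBM")


def main() -> None:
    for preset in PRESETS:
        cohort = COHORT_DIR / preset
        if not cohort.exists():
            raise SystemExit(f"{cohort} missing - run 01_simulate_cohorts.py")
        feats = compute_feature_table(read_object_dir(cohort))
        write_table(feats, RESULTS / f"features_{preset}.csv")
        big = (feats["area_bf_um2"] >= 50).sum()
        print(f"[{preset}] {len(feats)} objects; "
              f"{big} above the 50 um^2 multiplet cut; "
              f"median area {feats['area_bf_um2'].median():.1f} um^2")


if __name__ == "__main__":
    main()
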