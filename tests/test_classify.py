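"""Segmentation and rule-based cluster classification against planted truth."""

from __future__ import annotations

import numpy as np
import pytest

from ebiflow import (ClassifyConfig, classify_cluster, coexpression_call,
                     count_cd11b_cells, object_mask, positivity,
                     preset_config, segment_cells, simulate_object)
from ebiflow.classify import positivity_threshold
from ebiflow.features import S_CAP
from ebiflow.simulate import NoiseModel
from ebiflow.pipeline import run_cohort

from conftest import collapse_truth


def _rng(seed):
    return np.random.default_rng(seed)


class TestSegmentCells:
    def test_planted_nuclei_recovered_without_noise(self):
        cfg = preset_config("BM", erythroblasts_per_EBI=(5, 5),
                            p_cd11b_satellite=0.0,
                            noise=NoiseModel(0.0, 0.0, 0.0))
        img, _ = simulate_object(cfg, "EBI", _rng(3))
        cells = segment_cells(img)
        assert len(cells) == 6  # 5 erythroblasts + macrophage

    def test_singlet_yields_exactly_one_cell(self):
        cfg = preset_config("BM")
        img, _ = simulate_object(cfg, "singlet_erythroblast", _rng(4))
        assert len(segment_cells(img)) == 1

    def test_debris_yields_no_cells(self):
        cfg = preset_config("BM")
        img, _ = simulate_object(cfg, "debris", _rng(5))
        assert segment_cells(img) == []

    def test_nucleus_count_within_one_for_most_noisy_objects(self, bm_merged):
        clusters = bm_merged[bm_merged["true_class"].isin(
            ["EBI", "loose_cluster", "VCAM1pos_F480lo_cluster"])]
        close = (clusters["n_nuclei"] - clusters["n_nuclei_true"]).abs() <= 1
        assert close.mean() >= 0.90


class TestClassifyCluster:
    def test_planted_classes_recovered(self, bm_merged):
        acc = (bm_merged["call"] == bm_merged["truth_call"]).mean()
        assert acc >= 0.9

    def test_planted_ebi_called_ebi(self):
        cfg = preset_config("BM", erythroblasts_per_EBI=(5, 5))
        img, _ = simulate_object(cfg, "EBI", _rng(6))
        call = classify_cluster(img, segment_cells(img))
        assert call.call == "EBI"
        assert call.central_present and call.n_erythroblasts >= 3

    def test_planted_vcam_cluster_called_vcam(self):
        cfg = preset_config("FL")
        img, _ = simulate_object(cfg, "VCAM1pos_F480lo_cluster", _rng(7))
        call = classify_cluster(img, segment_cells(img))
        assert call.call == "VCAM1pos_F480lo_cluster"

    def test_planted_rat_ebi_called_ebi_on_cd163_axis(self):
        cfg = preset_config("ratBM", erythroblasts_per_EBI=(6, 6))
        rat = ClassifyConfig(species="rat")
        img, _ = simulate_object(cfg, "EBI", _rng(12))
        call = classify_cluster(img, segment_cells(img, cfg=rat), rat)
        assert call.call == "EBI"
        assert call.central_markers["CD163"] == "positive"
        assert call.central_markers.get("CD169", "negative") == "negative"

    def test_planted_loose_aggregate_called_loose(self):
        cfg = preset_config("BM")
        hits = 0
        for seed in range(8):
            img, _ = simulate_object(cfg, "loose_cluster", _rng(100 + seed))
            if classify_cluster(img, segment_cells(img)).call == "loose_cluster":
                hits += 1
        assert hits >= 7

    def test_ebi_call_implies_structure(self, bm_run):
        calls = bm_run["calls"]
        ebis = calls[calls["call"] == "EBI"]
        assert (ebis["central_present"]).all()
        assert (ebis["n_erythroblasts"] >= 3).all()
        assert (calls["n_erythroblasts"] <= calls["n_nuclei"]).all()

    def test_accuracy_degrades_gracefully_with_noise(self):
        accs = []
        for sd in (2.0, 8.0, 32.0):
            cfg = preset_config("BM", n_objects=120, seed=77,
                                noise=NoiseModel(gaussian_sd=sd))
            res = run_cohort(cfg)
            m = res["calls"].merge(res["truth"], on="object_id",
                                   suffixes=("", "_true"))
            accs.append((m["call"] == m["true_class"].map(collapse_truth)).mean())
        assert accs[0] >= accs[1] >= accs[2]


class TestCd11bAccounting:
    def test_planted_satellites_counted_centre_negative(self):
        cfg = preset_config("BM", cd11b_satellites_per_EBI=(2, 2),
                            p_cd11b_satellite=1.0)
        img, truth = simulate_object(cfg, "EBI", _rng(8))
        cells = segment_cells(img)
        call = classify_cluster(img, cells)
        assert call.n_cd11b_cells == 2
        assert call.central_cd11b_positive is False

    def test_missing_channel_flagged_not_counted(self):
        cfg = preset_config("BM")
        img, _ = simulate_object(cfg, "EBI", _rng(9))
        del img.channels["CD11b"]
        omask = object_mask(img, "BF")
        cells = segment_cells(img, omask)
        n, central = count_cd11b_cells(img, cells, ClassifyConfig(), omask, None)
        assert n is None and central is None
        call = classify_cluster(img, cells)
        assert "no_cd11b_channel" in call.flags

    def test_satellite_rate_matches_planted_probability(self, bm_merged):
        ebis = bm_merged[(bm_merged["true_class"] == "EBI")
                         & (bm_merged["call"] == "EBI")]
        frac = (ebis["n_cd11b_cells"].astype(float) >= 1).mean()
        p = 0.8
        sd = np.sqrt(p * (1 - p) / len(ebis))
        assert abs(frac - p) <= 3 * sd


class TestPositivity:
    def test_threshold_is_inclusive(self):
        assert positivity(10.0, 10.0) == "positive"
        assert positivity(9.999, 10.0) == "negative"
        assert positivity(float("nan"), 10.0) == "undefined"

    def test_zero_signal_channel_rarely_positive(self, bm_run):
        # CD163 carries no signal in the mouse presets; cells should be
        # called negative for it essentially always
        cfg = ClassifyConfig()
        n_pos = n_tot = 0
        for img in bm_run["images"][:60]:
            omask = object_mask(img, "BF")
            if omask.is_empty:
                continue
            thr = positivity_threshold(img, "CD163", omask, cfg)
            for cell in segment_cells(img, omask, cfg):
                mp = float(img.channel("CD163")[cell.footprint].mean())
                n_tot += 1
                n_pos += positivity(mp, thr) == "positive"
        assert n_tot > 50
        assert n_pos / n_tot <= 0.01

    def test_patchy_cd169_called_positive_on_most_ebi_macrophages(self, bm_merged):
        ebis = bm_merged[(bm_merged["true_class"] == "EBI")
                         & (bm_merged["call"] == "EBI")]
        assert (ebis["central_CD169"] == "positive").mean() >= 0.90


class TestCoexpression:
    def test_extreme_scores(self):
        assert coexpression_call(S_CAP) == "consistent"
        assert coexpression_call(-S_CAP) == "inconsistent"
        assert coexpression_call(float("nan")) == "undefined"

    def test_separates_coexpressed_from_disjoint_markers(self, bm_merged):
        # VCAM-1 shares the macrophage footprint with F4/80; CD11b sits on
        # other cells entirely.  The similarity cut must separate the two.
        ebis = bm_merged[(bm_merged["true_class"] == "EBI")
                         & (bm_merged["call"] == "EBI")]
        co = ebis["similarity_VCAM1"].dropna().map(coexpression_call)
        dis = ebis["similarity_CD11b"].dropna().map(coexpression_call)
        correct = (co == "consistent").sum() + (dis == "inconsistent").sum()
        assert correct / (len(co) + len(dis)) >= 0.95
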