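"""Rule-based organ correction, epithelium geometry and threshold calibration."""

import logging

import numpy as np
import pytest

import histoblocks as hb
from histoblocks.knowledge_base import HAS_PRESENCE_OF, KnowledgeBase


def heart_matrix_with_stray_ea(n_stray=5):
    """20x15-style matrix dominated by HE with a few stray EA cells."""
    labels = np.full((15, 20), "HE", dtype="U2")
    labels[:3, :] = "LC"
    cells = [(7, 2), (8, 2), (9, 4), (10, 17), (12, 18)][:n_stray]
    for c in cells:
        labels[c] = "EA"
    return hb.LabelMatrix(labels), cells


class TestOccurrences:
    def test_all_lc_matrix_counts_zero(self):
        m = hb.LabelMatrix(np.full((15, 20), "LC", dtype="U2"))
        assert hb.count_occurrences(m) == {"EA": 0, "LV": 0, "MA": 0, "HE": 0}

    def test_direct_count(self):
        labels = np.full((15, 20), "LC", dtype="U2")
        labels[:6, :] = "HE"          # 120 cells
        labels[14, :5] = "EA"         # 5 cells
        counts = hb.count_occurrences(hb.LabelMatrix(labels))
        assert counts == {"HE": 120, "EA": 5, "LV": 0, "MA": 0}

    def test_transposition_invariant(self):
        labels = np.full((6, 4), "LC", dtype="U2")
        labels[0, :] = "MA"
        m = hb.LabelMatrix(labels)
        mt = hb.LabelMatrix(labels.T)
        assert hb.count_occurrences(m) == hb.count_occurrences(mt)


class TestRanking:
    def test_descending_by_count(self):
        ranked = hb.rank_organs({"HE": 120, "EA": 5, "LV": 0, "MA": 0})
        assert ranked == ["Heart", "ElasticArtery"]

    def test_all_zero_gives_empty(self):
        assert hb.rank_organs({"HE": 0, "EA": 0, "LV": 0, "MA": 0}) == []

    def test_tie_broken_by_priority_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            ranked = hb.rank_organs({"EA": 7, "LV": 7, "HE": 0, "MA": 0})
        assert ranked == ["ElasticArtery", "LargeVein"]
        assert any("tie" in r.message for r in caplog.records)


class TestRules:
    def test_single_pair(self):
        rules = hb.build_rules(["Heart", "ElasticArtery"])
        assert [(r.subject, r.predicate, r.obj) for r in rules] == \
            [("Heart", HAS_PRESENCE_OF, "ElasticArtery")]

    def test_single_organ_no_rules(self):
        assert hb.build_rules(["Heart"]) == []

    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4])
    def test_pair_count_law(self, k):
        organs = ["Heart", "LargeVein", "ElasticArtery", "MuscularArtery"][:k]
        assert len(hb.build_rules(organs)) == k * (k - 1) // 2

    def test_worked_four_organ_list(self):
        # ranking heart > large vein > elastic artery > muscular artery
        # must include the four classic queries (heart->EA, heart->LV,
        # LV->EA, LV->MA).
        rules = hb.build_rules(
            ["Heart", "LargeVein", "ElasticArtery", "MuscularArtery"]
        )
        triples = {(r.subject, r.obj) for r in rules}
        assert {("Heart", "ElasticArtery"), ("Heart", "LargeVein"),
                ("LargeVein", "ElasticArtery"),
                ("LargeVein", "MuscularArtery")} <= triples
        assert len(rules) == 6


class TestApplyRules:
    def test_stray_organ_cells_become_loose_connective(self, kb):
        matrix, cells = heart_matrix_with_stray_ea()
        rules = hb.build_rules(hb.rank_organs(hb.count_occurrences(matrix)))
        out = hb.apply_rules(matrix, rules, kb)
        for c in cells:
            assert out.labels[c] == "LC"
            assert out.provenance[c] == "corrected"
        assert (out.labels == "EA").sum() == 0
        # untouched cells keep label and provenance
        assert (out.labels[:3] == "LC").all()
        assert (out.labels == "HE").sum() == (matrix.labels == "HE").sum()

    def test_single_organ_matrix_unchanged(self, kb):
        labels = np.full((5, 5), "MA", dtype="U2")
        m = hb.LabelMatrix(labels)
        rules = hb.build_rules(hb.rank_organs(hb.count_occurrences(m)))
        assert hb.apply_rules(m, rules, kb) == m

    def test_asserted_presence_preserves_cells(self):
        kb = KnowledgeBase([("Heart", HAS_PRESENCE_OF, "ElasticArtery")])
        matrix, cells = heart_matrix_with_stray_ea()
        rules = hb.build_rules(hb.rank_organs(hb.count_occurrences(matrix)))
        out = hb.apply_rules(matrix, rules, kb)
        for c in cells:
            assert out.labels[c] == "EA"


class TestLightComponents:
    def test_run_of_nine_rejected_ten_accepted(self):
        labels = np.full((15, 20), "LC", dtype="U2")
        labels[5, 3:12] = "LR"   # 9 consecutive blocks
        assert hb.find_light_components(hb.LabelMatrix(labels)) == []
        labels[5, 3:13] = "LR"   # 10 consecutive blocks
        comps = hb.find_light_components(hb.LabelMatrix(labels))
        assert len(comps) == 1 and comps[0].size == 10

    def test_l_shape_is_one_component(self):
        labels = np.full((15, 20), "LC", dtype="U2")
        labels[4:10, 5] = "LR"
        labels[9, 5:11] = "LR"
        comps = hb.find_light_components(hb.LabelMatrix(labels))
        assert len(comps) == 1 and comps[0].size == 11

    def test_diagonal_cells_are_separate_components(self):
        labels = np.full((15, 20), "LC", dtype="U2")
        labels[2:4, 2:8] = "LR"       # 12-cell rectangle
        labels[4, 8] = "LR"           # diagonal touch only
        comps = hb.find_light_components(hb.LabelMatrix(labels), min_size=1)
        assert sorted(c.size for c in comps) == [1, 12]

    def test_sorted_by_size_descending(self):
        labels = np.full((15, 20), "LC", dtype="U2")
        labels[1, 0:10] = "LR"
        labels[5:9, 14:18] = "LR"
        comps = hb.find_light_components(hb.LabelMatrix(labels))
        assert [c.size for c in comps] == [16, 10]


class TestQualification:
    def test_component_in_connective_does_not_qualify(self):
        labels = np.full((15, 20), "LC", dtype="U2")
        labels[5, 3:13] = "LR"
        m = hb.LabelMatrix(labels)
        comp = hb.find_light_components(m)[0]
        assert not hb.qualifies_for_epithelium(comp, m)

    def test_single_muscle_neighbor_qualifies(self):
        labels = np.full((15, 20), "LC", dtype="U2")
        labels[5, 3:13] = "LR"
        labels[4, 5] = "MA"
        m = hb.LabelMatrix(labels)
        comp = hb.find_light_components(m)[0]
        assert hb.qualifies_for_epithelium(comp, m)

    def test_border_only_component_does_not_qualify(self):
        labels = np.full((15, 20), "LC", dtype="U2")
        labels[0, :] = "LR"   # touches only the matrix border and LC
        m = hb.LabelMatrix(labels)
        comp = hb.find_light_components(m)[0]
        assert not hb.qualifies_for_epithelium(comp, m)


def lumen_fixture(organ_label="EA"):
    """LR lumen inside a muscle annulus inside connective surround."""
    gt = hb.generate_organ_image(hb.OrganLayout(
        organ={"EA": "ElasticArtery", "HE": "Heart"}[organ_label],
        lumen_radius=3.0, seed=42,
    ))
    pred = gt.truth.copy()
    pred.labels[pred.labels == "EP"] = "LR"   # classifier-level view
    pred.provenance[:] = "classifier"
    return pred, gt.truth


class TestDetectEpithelium:
    def test_ring_appears_at_lumen_muscle_interface(self, kb):
        pred, truth = lumen_fixture()
        out = hb.detect_epithelium(pred, kb)
        assert out == truth
        assert (out.provenance[out.labels == "EP"] == "epithelium").all()
        # interior LR cells stay LR
        assert (out.labels == "LR").sum() == (truth.labels == "LR").sum()

    def test_no_light_regions_unchanged(self, kb):
        m = hb.LabelMatrix(np.full((5, 5), "HE", dtype="U2"))
        assert hb.detect_epithelium(m, kb) == m

    def test_empty_epithelium_answer_unchanged(self):
        pred, _ = lumen_fixture()
        assert hb.detect_epithelium(pred, KnowledgeBase()) == pred

    def test_ep_only_on_lr_muscle_boundary(self, kb):
        pred, _ = lumen_fixture()
        out = hb.detect_epithelium(pred, kb)
        m, n = out.shape
        for i in range(m):
            for j in range(n):
                if out.labels[i, j] != "EP":
                    continue
                assert pred.labels[i, j] == "LR"
                neighbors = [
                    pred.labels[i + di, j + dj]
                    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
                    if 0 <= i + di < m and 0 <= j + dj < n
                ]
                assert any(x in hb.DISCRIMINANT_LABELS for x in neighbors)


class TestRefine:
    def test_idempotent(self, kb):
        pred, _ = lumen_fixture()
        corrupted, _ = hb.corrupt_matrix(pred_to_truth(pred), 0.1, 3,
                                         "ElasticArtery")
        for matrix in (pred, corrupted):
            once = hb.refine(matrix, kb)
            assert hb.refine(once, kb) == once

    def test_clean_fixture_only_gains_ep_ring(self, kb):
        pred, truth = lumen_fixture()
        assert hb.refine(pred, kb) == truth

    def test_corruption_and_ep_both_fixed(self, kb):
        pred, truth = lumen_fixture()
        pred.labels[0, 0] = pred.labels[0, 1] = "HE"  # stray foreign organ
        out = hb.refine(pred, kb)
        assert out.labels[0, 0] == out.labels[0, 1] == "LC"
        assert (out.labels == "EP").sum() == (truth.labels == "EP").sum()

    def test_label_conservation(self, kb):
        pred, truth = lumen_fixture()
        for seed in range(5):
            corrupted, _ = hb.corrupt_matrix(truth, 0.15, seed,
                                             "ElasticArtery")
            out = hb.refine(corrupted, kb)
            changed = corrupted.labels != out.labels
            for a, b in zip(corrupted.labels[changed], out.labels[changed]):
                assert (a in hb.DISCRIMINANT_LABELS and b == "LC") or \
                    (a == "LR" and b == "EP")


def pred_to_truth(pred):
    # helper: reuse a pred matrix as a stand-in truth for corruption
    return pred


class TestCalibration:
    def test_zero_residual_candidate_wins(self, kb):
        pred, truth = hb.generate_calibration_matrices(seed=0)
        problem = hb.CalibrationProblem(
            candidates=range(2, 21), pairs=[(pred, truth)], kb=kb
        )
        assert hb.calibrate_threshold(problem) == 10

    def test_tie_resolved_to_smaller_t(self, kb):
        # one LR component of 12 cells: every t in 2..12 reproduces the
        # truth exactly, so the smallest candidate wins
        labels = np.full((15, 20), "MA", dtype="U2")
        labels[5:8, 5:9] = "LR"
        pred = hb.LabelMatrix(labels)
        truth = hb.refine(pred, kb, min_size=12)
        problem = hb.CalibrationProblem(
            candidates=range(2, 13), pairs=[(pred, truth)], kb=kb
        )
        assert hb.calibrate_threshold(problem) == 2

    def test_empty_candidates_rejected(self, kb):
        with pytest.raises(ValueError, match="empty"):
            hb.calibrate_threshold(
                hb.CalibrationProblem(candidates=[], pairs=[], kb=kb)
            )

    def test_recovers_generating_threshold_across_seeds(self, kb):
        hits = 0
        for seed in range(10):
            pred, truth = hb.generate_calibration_matrices(seed=seed)
            problem = hb.CalibrationProblem(
                candidates=range(2, 21), pairs=[(pred, truth)], kb=kb
            )
            hits += hb.calibrate_threshold(problem) == 10
        assert hits == 10
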