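"""Efficacy indices, ROC, cutoff scan and the selection algorithm."""

import math

import numpy as np
import pytest
from scipy.stats import rankdata

from igdscreen import (ConfusionTable, classify, confusion_table,
                       efficacy_indices, roc_auc, scan_cutoffs,
                       select_optimal_cutoff)
from igdscreen.screening import (CutoffScan, EfficacyIndices,
                                 reconstruct_confusion_tables, round_half_up,
                                 scores_from_tables)

# counts behind the published cutoff rows, re-derived by exhaustive search
# in TestReconstruction before anything else trusts them
EXPECTED_TABLES = {
    16: (55, 109, 5, 295), 17: (54, 87, 6, 317), 18: (54, 79, 6, 325),
    19: (52, 70, 8, 334), 20: (49, 59, 11, 345), 21: (46, 52, 14, 352),
    22: (41, 39, 19, 365),
}


def rank_pair_auc(scores, labels):
    """Independent oracle: rank statistic with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    r = rankdata(scores)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    return (r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


class TestConfusionTable:
    def test_all_below_cutoff(self):
        t = confusion_table([1, 2, 3], [1, 0, 1], cutoff=10)
        assert (t.tp, t.fp) == (0, 0)
        assert t.fn == 2 and t.tn == 1

    def test_cutoff_at_minimum_makes_everyone_positive(self):
        t = confusion_table([4, 5, 6], [0, 1, 0], cutoff=4)
        assert (t.fn, t.tn) == (0, 0)

    def test_ten_person_hand_count(self):
        scores = [10, 12, 15, 15, 18, 20, 22, 25, 8, 30]
        ref = [0, 0, 1, 0, 1, 0, 1, 1, 0, 1]
        t = confusion_table(scores, ref, cutoff=18)
        assert (t.tp, t.fp, t.fn, t.tn) == (4, 1, 1, 4)
        assert t.positives == 5 and t.negatives == 5 and t.n == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_table([], [], 5)


class TestEfficacyIndices:
    def test_published_optimal_cutoff_row(self):
        ix = efficacy_indices(ConfusionTable(tp=49, fp=59, fn=11, tn=345))
        assert round_half_up(ix.sensitivity, 1) == 81.7
        assert round_half_up(ix.specificity, 1) == 85.4
        assert round_half_up(ix.ppr, 1) == 45.4
        assert round_half_up(ix.npr, 1) == 96.9
        assert round_half_up(ix.kappa, 2) == 0.50
        assert round_half_up(ix.youden, 2) == 0.67

    def test_perfect_test(self):
        ix = efficacy_indices(ConfusionTable(tp=10, fp=0, fn=0, tn=10))
        assert ix.sensitivity == ix.specificity == 100.0
        assert ix.kappa == pytest.approx(1.0)
        assert ix.youden == pytest.approx(1.0)

    def test_hand_computed_small_table(self):
        ix = efficacy_indices(ConfusionTable(tp=2, fp=3, fn=1, tn=4))
        assert ix.sensitivity == pytest.approx(66.667, abs=1e-2)
        assert ix.specificity == pytest.approx(57.143, abs=1e-2)
        assert ix.kappa == pytest.approx(0.20, abs=1e-9)
        assert ix.youden == pytest.approx(0.2381, abs=1e-4)
        assert ix.dor == pytest.approx(8 / 3, abs=1e-9)

    def test_youden_identity(self):
        ix = efficacy_indices(ConfusionTable(tp=7, fp=4, fn=3, tn=16))
        assert ix.youden == pytest.approx(
            ix.sensitivity / 100 + ix.specificity / 100 - 1, abs=1e-12)

    def test_haldane_correction_only_with_zero_cell(self):
        with_zero = efficacy_indices(ConfusionTable(tp=5, fp=0, fn=2, tn=10))
        assert with_zero.dor == pytest.approx((5.5 * 10.5) / (0.5 * 2.5))
        without = efficacy_indices(ConfusionTable(tp=5, fp=1, fn=2, tn=10))
        assert without.dor == pytest.approx(50 / 2)

    def test_undefined_ratio_flagged_not_zeroed(self):
        ix = efficacy_indices(ConfusionTable(tp=0, fp=0, fn=6, tn=14))
        assert math.isnan(ix.ppr)
        assert "ppr" in ix.undefined

    def test_kappa_one_iff_no_errors(self):
        perfect = efficacy_indices(ConfusionTable(tp=3, fp=0, fn=0, tn=7))
        assert perfect.kappa == pytest.approx(1.0)
        flawed = efficacy_indices(ConfusionTable(tp=3, fp=1, fn=0, tn=6))
        assert flawed.kappa < 1.0

    def test_kappa_near_zero_under_independence(self, rng):
        screen = rng.random(10_000) < 0.3
        ref = rng.random(10_000) < 0.2
        t = ConfusionTable(tp=int((screen & ref).sum()),
                           fp=int((screen & ~ref).sum()),
                           fn=int((~screen & ref).sum()),
                           tn=int((~screen & ~ref).sum()))
        assert abs(efficacy_indices(t).kappa) < 0.02


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_uninformative_scores(self):
        auc, _ = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_small_tie_example(self):
        auc, _ = roc_auc([1, 2, 2, 3], [0, 0, 1, 1])
        assert auc == pytest.approx(0.875)

    def test_trapezoid_equals_rank_pair_statistic(self, rng):
        for _ in range(200):
            n = rng.integers(10, 60)
            scores = rng.integers(0, 20, size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(rank_pair_auc(scores, labels),
                                        abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestScan:
    def test_rows_match_individual_confusion_tables(self, rng):
        scores = rng.integers(0, 54, size=300)
        ref = rng.integers(0, 2, size=300)
        scan = scan_cutoffs(scores, ref, range(5, 40))
        for cutoff, table, _ in scan.rows:
            assert table == confusion_table(scores, ref, cutoff)

    def test_monotone_sensitivity_and_specificity(self, rng):
        scores = rng.integers(0, 54, size=500)
        ref = (scores + rng.normal(0, 10, 500) > 30).astype(int)
        scan = scan_cutoffs(scores, ref, range(1, 54))
        sens = [ix.sensitivity for _, _, ix in scan.rows]
        spec = [ix.specificity for _, _, ix in scan.rows]
        assert all(b <= a + 1e-9 for a, b in zip(sens, sens[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(spec, spec[1:]))

    def test_marginals_conserved_at_every_cutoff(self, published_scan_data):
        scores, ref = published_scan_data
        scan = scan_cutoffs(scores, ref, range(16, 23))
        for _, table, _ in scan.rows:
            assert table.positives == 60
            assert table.negatives == 404

    def test_width_one_range(self):
        scan = scan_cutoffs([1, 5, 9], [0, 1, 1], [5])
        assert scan.cutoffs == [5]

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scan_cutoffs([1, 2], [0, 1], [])


class TestReconstruction:
    def test_exhaustive_search_finds_unique_published_tables(self,
                                                             published_tables):
        for cutoff, (tp, fp, fn, tn) in EXPECTED_TABLES.items():
            t = published_tables[cutoff]
            assert (t.tp, t.fp, t.fn, t.tn) == (tp, fp, fn, tn)

    def test_scan_of_synthesized_scores_reproduces_tables(self,
                                                          published_scan_data,
                                                          published_tables):
        scores, ref = published_scan_data
        scan = scan_cutoffs(scores, ref, range(16, 23))
        for cutoff, table, _ in scan.rows:
            assert table == published_tables[cutoff]


class TestSelection:
    def test_published_scan_selects_twenty(self, published_scan_data):
        scores, ref = published_scan_data
        scan = scan_cutoffs(scores, ref, range(16, 23))
        sel = select_optimal_cutoff(scan)
        assert sel.candidates == [17, 18, 19, 20, 21]
        assert sel.kappa_max_set == [20, 21]
        assert sel.selected == 20

    def test_single_admissible_row(self):
        scan = scan_cutoffs([10, 20, 20, 30, 5, 5, 6], [0, 1, 1, 1, 0, 0, 0],
                            [15])
        sel = select_optimal_cutoff(scan)
        assert sel.selected == 15

    def test_no_admissible_cutoff_is_explicit(self, published_scan_data):
        scores, ref = published_scan_data
        scan = scan_cutoffs(scores, ref, range(16, 23))
        sel = select_optimal_cutoff(scan, min_sens=99.9, min_spec=99.9)
        assert sel.selected is None
        assert sel.candidates == []
        assert sel.audit[-1]["reason"] == "no admissible cutoff"

    def test_strict_inequality_excludes_boundary_row(self, published_scan_data):
        # the published row at cutoff 16 has specificity 73.0 < 75: excluded
        scores, ref = published_scan_data
        scan = scan_cutoffs(scores, ref, range(16, 23))
        sel = select_optimal_cutoff(scan)
        assert 16 not in sel.candidates

    def test_rounded_kappa_rule_beats_unrounded_ordering(self):
        def row(cutoff, sens, spec, kappa, youden, dor):
            ix = EfficacyIndices(sensitivity=sens, specificity=spec,
                                 ppr=50.0, npr=90.0, kappa=kappa,
                                 youden=youden, dor=dor)
            return (cutoff, ConfusionTable(tp=1, fp=1, fn=1, tn=1), ix)

        # unrounded kappa prefers 21, but both round to 0.50 and the
        # sensitivity tie-break then prefers 20
        scan = CutoffScan(rows=[row(20, 82.0, 85.0, 0.4980, 0.67, 26.0),
                                row(21, 77.0, 87.0, 0.5021, 0.64, 22.0)])
        sel = select_optimal_cutoff(scan)
        assert sel.kappa_max_set == [20, 21]
        assert sel.selected == 20
        kappa_step = next(s for s in sel.audit if s["step"] == "kappa")
        assert kappa_step["rounded_kappa"] == {20: 0.50, 21: 0.50}

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_optimal_cutoff(CutoffScan(rows=[]))


class TestClassify:
    def test_positive_proportion_at_published_cutoff(self, published_scan_data):
        scores, _ = published_scan_data
        _, sizes = classify(scores, 20)
        assert sizes["positive"] == 108
        assert round_half_up(100 * sizes["positive"] / len(scores), 1) == 23.3

    def test_cutoff_above_maximum(self):
        labels, sizes = classify([1, 2, 3], 99)
        assert labels.sum() == 0 and sizes["negative"] == 3

    def test_complements_sum_to_n(self, rng):
        scores = rng.integers(0, 54, size=200)
        _, sizes = classify(scores, 20)
        assert sizes["positive"] + sizes["negative"] == 200
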