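"""Evaluation-suite tests: closed-form cases, brute-force oracles, bands."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octseg.metrics import (ConfusionCounts, EmptyMaskError, binarize,
                            confusion, evaluate, extract_boundary, hausdorff,
                            mean_absolute_error, overlap_metrics)

from oracles import (brute_boundary, brute_confusion, brute_hausdorff,
                     brute_mae, brute_overlap_metrics, random_mask_pair)


class TestBinarize:
    def test_threshold_is_inclusive(self):
        m = binarize(np.full((4, 4), 0.5), 0.5)
        assert m.all()

    def test_all_zero_map_is_empty(self):
        assert binarize(np.zeros((4, 4)), 0.5).sum() == 0

    @pytest.mark.parametrize("thr", [0.1, 0.5, 0.9])
    def test_idempotent_on_binary_input(self, thr):
        rng = np.random.default_rng(0)
        truth = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        assert np.array_equal(binarize(truth.astype(float), thr), truth)

    def test_rejects_degenerate_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 0.0)


class TestConfusion:
    def test_identical_masks(self):
        rng = np.random.default_rng(1)
        m = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        c = confusion(m, m)
        k = int(m.sum())
        assert (c.tp, c.tn, c.fp, c.fn) == (k, 64 - k, 0, 0)

    def test_all_foreground_prediction(self):
        truth = np.zeros((4, 4), np.uint8)
        truth[1, 1] = truth[2, 3] = 1
        c = confusion(np.ones((4, 4), np.uint8), truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 14, 0, 0)

    def test_matches_per_pixel_tally(self):
        rng = np.random.default_rng(2)
        pred, truth = random_mask_pair(rng, (8, 8))
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == brute_confusion(pred, truth)
        assert c.n == 64

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        pred, truth = random_mask_pair(rng)
        a, b = confusion(pred, truth), confusion(truth, pred)
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fn, b.fp)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))


class TestOverlapMetrics:
    def test_worked_confusion_table(self):
        m = overlap_metrics(ConfusionCounts(tp=6, fp=2, fn=2, tn=6))
        assert m["dice"] == pytest.approx(0.75)
        assert m["jaccard"] == pytest.approx(0.6)
        assert m["dice"] == pytest.approx(2 * m["jaccard"] / (1 + m["jaccard"]))

    def test_perfect_prediction_scores_one(self):
        m = overlap_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=6))
        assert all(v == 1.0 for v in m.values())

    def test_disjoint_masks_score_zero(self):
        m = overlap_metrics(ConfusionCounts(tp=0, fp=3, fn=4, tn=9))
        assert m["dice"] == 0.0 and m["jaccard"] == 0.0

    def test_empty_prediction_warns_nan_precision(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            m = overlap_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=13))
        assert np.isnan(m["precision"])

    def test_both_empty_agree_perfectly(self):
        with pytest.warns(RuntimeWarning):
            m = overlap_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=16))
        assert m["dice"] == 1.0 and m["jaccard"] == 1.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            overlap_metrics(ConfusionCounts(0, 0, 0, 0))


class TestMAE:
    def test_identical_masks_zero(self):
        m = np.eye(4, dtype=np.uint8)
        assert mean_absolute_error(m, m) == 0.0

    def test_two_of_sixteen_pixels(self):
        a = np.zeros((4, 4), np.uint8)
        b = a.copy()
        b[0, 0] = b[3, 3] = 1
        assert mean_absolute_error(a, b) == pytest.approx(0.125)

    def test_equals_fp_plus_fn_over_n(self):
        rng = np.random.default_rng(4)
        pred, truth = random_mask_pair(rng)
        c = confusion(pred, truth)
        assert mean_absolute_error(pred, truth) == pytest.approx(
            (c.fp + c.fn) / c.n)

    def test_soft_mode_accepts_probabilities(self):
        pred = np.full((2, 2), 0.25)
        truth = np.zeros((2, 2), np.uint8)
        assert mean_absolute_error(pred, truth, soft=True) == pytest.approx(0.25)


class TestBoundary:
    def test_single_pixel_is_its_own_boundary(self):
        m = np.zeros((5, 5), np.uint8)
        m[2, 2] = 1
        assert extract_boundary(m).tolist() == [[2, 2]]

    def test_interior_block_perimeter(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:6, 2:6] = 1
        assert len(extract_boundary(m)) == 12  # 4x4 block: ring of 12

    def test_full_image_boundary_is_border(self):
        m = np.ones((5, 6), np.uint8)
        pts = set(map(tuple, extract_boundary(m)))
        border = {(i, j) for i in range(5) for j in range(6)
                  if i in (0, 4) or j in (0, 5)}
        assert pts == border

    def test_empty_mask_gives_empty_set(self):
        assert len(extract_boundary(np.zeros((4, 4), np.uint8))) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m, _ = random_mask_pair(rng, (12, 12))
            assert set(map(tuple, extract_boundary(m))) == set(brute_boundary(m))


class TestHausdorff:
    def test_three_four_five_triangle(self):
        assert hausdorff([(0, 0)], [(3, 4)]) == pytest.approx(5.0)

    def test_zero_iff_equal_sets(self):
        pts = [(0, 0), (1, 2), (5, 5)]
        assert hausdorff(pts, pts) == 0.0

    def test_directed_maximum_dominates(self):
        assert hausdorff([(0, 0), (0, 10)], [(0, 0)]) == pytest.approx(10.0)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 20, (7, 2))
        b = rng.integers(0, 20, (5, 2))
        assert hausdorff(a, b) == pytest.approx(hausdorff(b, a))

    def test_translation_changes_distance_by_at_most_shift(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 20, (6, 2)).astype(float)
        b = rng.integers(0, 20, (6, 2)).astype(float)
        base = hausdorff(a, b)
        v = np.array([3.0, -2.0])
        shifted = hausdorff(a, b + v)
        assert abs(shifted - base) <= np.hypot(*v) + 1e-12

    def test_empty_operands_raise_distinct_errors(self):
        with pytest.raises(EmptyMaskError, match="prediction"):
            hausdorff(np.empty((0, 2)), [(0, 0)])
        with pytest.raises(EmptyMaskError, match="truth"):
            hausdorff([(0, 0)], np.empty((0, 2)))


class TestEvaluate:
    def test_perfect_prediction_full_report(self):
        m = np.zeros((10, 10), np.uint8)
        m[3:6, 2:9] = 1
        rep = evaluate(m, m)
        assert rep.dice == 1.0 and rep.hausdorff == 0.0
        assert rep.bands["dice"] == "excellent"

    def test_mae_band_good_below_one(self):
        from octseg.metrics import _band_mae, _band_hausdorff
        assert _band_mae(0.5) == "good"
        assert _band_mae(1.2) == "acceptable"
        assert _band_hausdorff(40.0) == "acceptable"
        assert _band_hausdorff(10.0) == "good"
        assert _band_hausdorff(80.0) == "poor"

    def test_report_matches_component_calls(self):
        rng = np.random.default_rng(8)
        pred, truth = random_mask_pair(rng, (12, 12))
        rep = evaluate(pred, truth)
        assert rep.mae == pytest.approx(brute_mae(pred, truth))
        assert rep.dice == pytest.approx(
            brute_overlap_metrics(pred, truth)["dice"])


def test_oracle_equivalence_random_pairs():
    """Every metric agrees with the brute-force reference on random masks."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        pred, truth = random_mask_pair(rng)
        rep = evaluate(pred, truth)
        exp = brute_overlap_metrics(pred, truth)
        for key, val in exp.items():
            assert getattr(rep, key) == pytest.approx(val, abs=1e-12)
        assert rep.mae == pytest.approx(brute_mae(pred, truth), abs=1e-12)
        assert rep.hausdorff == pytest.approx(
            brute_hausdorff(brute_boundary(pred), brute_boundary(truth)),
            abs=1e-12)


@given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50),
       tn=st.integers(1, 50))
@settings(deadline=None, derandomize=True, max_examples=200)
def test_dice_jaccard_identity_on_arbitrary_confusion_tables(tp, fp, fn, tn):
    """dice = 2J/(1+J) and dice >= jaccard for every confusion table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = overlap_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
    assert m["dice"] == pytest.approx(2 * m["jaccard"] / (1 + m["jaccard"]),
                                      abs=1e-12)
    assert m["dice"] >= m["jaccard"]


def test_accuracy_equals_one_minus_mae_on_binary_masks():
    rng = np.random.default_rng(9)
    for _ in range(20):
        pred, truth = random_mask_pair(rng)
        rep = evaluate(pred, truth)
        assert rep.accuracy == pytest.approx(1.0 - rep.mae, abs=1e-12)
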