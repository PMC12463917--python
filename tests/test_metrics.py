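"""Confusion counting and the five evaluation formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fruitdefect as fd
from fruitdefect import ConfusionCounts
from fruitdefect.errors import ExtentMismatchError
from oracles import best_assignment_tp, pixel_confusion_loops


class TestPixelConfusion:
    def test_perfect_prediction(self, rng):
        t = rng.random((30, 30)) > 0.6
        c = fd.pixel_confusion(t, t)
        m = fd.metrics(c)
        assert c.fp == 0 and c.fn == 0
        assert m.iou == 100.0 and m.dice == 100.0

    def test_empty_prediction_scores_zero_recall(self, rng):
        t = rng.random((30, 30)) > 0.6
        m = fd.metrics(fd.pixel_confusion(np.zeros_like(t), t))
        assert m.recognition_accuracy == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((20, 20)) > 0.5
        truth = rng.random((20, 20)) > 0.5
        domain = rng.random((20, 20)) > 0.2
        c = fd.pixel_confusion(pred, truth, domain)
        assert (c.tp, c.fp, c.fn, c.tn) == pixel_confusion_loops(pred, truth, domain)

    def test_domain_restriction_excludes_background(self, rng):
        pred = rng.random((20, 20)) > 0.5
        truth = rng.random((20, 20)) > 0.5
        domain = np.zeros((20, 20), dtype=bool)
        c = fd.pixel_confusion(pred, truth, domain)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 0)

    def test_extent_mismatch_rejected(self):
        with pytest.raises(ExtentMismatchError):
            fd.pixel_confusion(np.zeros((5, 5), bool), np.zeros((6, 6), bool))


def jittered_components(rng, n_truth, drop=0):
    shape = (80, 80)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    truths, preds = [], []
    grid = np.array([(y, x) for y in range(12, 68, 18) for x in range(12, 68, 18)])
    centers = grid[rng.choice(len(grid), size=n_truth, replace=False)]
    for cy, cx in centers:
        r = rng.integers(4, 8)
        truths.append((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r)
        jy, jx = rng.integers(-2, 3, size=2)
        preds.append((yy - cy - jy) ** 2 + (xx - cx - jx) ** 2 <= r * r)
    for _ in range(drop):
        preds.pop()
    return preds, truths


class TestRegionConfusion:
    def test_single_match(self, rng):
        preds, truths = jittered_components(rng, 1)
        c = fd.region_confusion(preds, truths)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_missed_truth_counts_as_fn(self, rng):
        preds, truths = jittered_components(rng, 2, drop=1)
        c = fd.region_confusion(preds, truths)
        assert (c.tp, c.fn) == (1, 1)
        assert fd.metrics(c).recognition_accuracy == 50.0

    @pytest.mark.parametrize("seed", range(25))
    def test_greedy_matching_is_optimal_on_small_scenes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 5))
        preds, truths = jittered_components(rng, n, drop=int(rng.integers(0, n)))
        c = fd.region_confusion(preds, truths, match_iou=0.3)
        assert c.tp == best_assignment_tp(preds, truths, 0.3)

    def test_region_tn_is_undefined(self, rng):
        preds, truths = jittered_components(rng, 2)
        c = fd.region_confusion(preds, truths)
        assert c.tn == 0
        if c.fp == 0:
            assert fd.metrics(c).fpr is None  # FPR unavailable at region level


class TestMetricFormulas:
    def test_recognition_accuracy_example(self):
        m = fd.metrics(ConfusionCounts(tp=39, fp=0, fn=1, tn=0))
        assert m.recognition_accuracy == pytest.approx(97.5)

    def test_iou_dice_example(self):
        m = fd.metrics(ConfusionCounts(tp=8, fp=1, fn=1, tn=0))
        assert m.iou == pytest.approx(80.0)
        assert m.dice == pytest.approx(88.888888, abs=1e-3)

    def test_zero_denominator_reports_undefined(self):
        m = fd.metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=0))
        assert m.recognition_accuracy is None
        assert m.iou is None and m.fpr is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    tp=st.integers(0, 10_000),
    fp=st.integers(0, 10_000),
    fn=st.integers(0, 10_000),
    tn=st.integers(0, 10_000),
)
def test_metric_identities(tp, fp, fn, tn):
    """recognition + FNR = 100 and Dice = 2*IoU/(1+IoU), whenever defined."""
    m = fd.metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
    if m.recognition_accuracy is not None:
        assert m.recognition_accuracy + m.fnr == pytest.approx(100.0)
    if m.iou is not None:
        iou = m.iou / 100.0
        assert m.dice / 100.0 == pytest.approx(2 * iou / (1 + iou))


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    tp=st.integers(0, 1000),
    fp=st.integers(0, 1000),
    fn=st.integers(0, 1000),
    tn=st.integers(0, 1000),
)
def test_pred_truth_swap_symmetry(tp, fp, fn, tn):
    """Swapping prediction and truth swaps FP and FN and preserves Dice."""
    a = fd.metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
    b = fd.metrics(ConfusionCounts(tp=tp, fp=fn, fn=fp, tn=tn))
    if a.dice is not None:
        assert a.dice == pytest.approx(b.dice)
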