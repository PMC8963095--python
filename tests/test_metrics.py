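"""Overlap metrics against an exhaustive voxel-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fissnet.grids import GridError
from fissnet.metrics import (ConfusionCounts, auc_balanced, confusion_counts, dice,
                             evaluate, overlap_coefficient, sensitivity, specificity)

from conftest import mask_from


def loop_oracle(p, g):
    """Independent exhaustive voxel loop computing every measure from scratch."""
    tp = tn = fp = fn = inter = 0
    np_, ng = 0, 0
    for pi, gi in zip(p.ravel().tolist(), g.ravel().tolist()):
        np_ += pi
        ng += gi
        inter += pi * gi
        if pi and gi:
            tp += 1
        elif pi and not gi:
            fp += 1
        elif not pi and gi:
            fn += 1
        else:
            tn += 1
    out = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    out["DSC"] = 2 * inter / (np_ + ng) if np_ + ng else 1.0
    out["OC"] = inter / min(np_, ng) if np_ and ng else None
    out["SP"] = tn / (fp + tn) if fp + tn else None
    out["SN"] = tp / (tp + fn) if tp + fn else None
    if out["SP"] is not None and out["SN"] is not None:
        out["AUC"] = 1 - 0.5 * (fp / (fp + tn) + fn / (fn + tp))
    return out


class TestConfusionCounts:
    def test_identical_masks_have_no_errors(self, rng):
        m = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(mask_from(m), mask_from(m))
        assert c.fp == 0 and c.fn == 0
        assert c.tp == int(m.sum())

    def test_complement_has_no_correct_voxels(self, rng):
        m = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(mask_from(1 - m), mask_from(m))
        assert c.tp == 0 and c.tn == 0

    def test_hand_placed_counts(self):
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        p = np.zeros((4, 4, 4), dtype=np.uint8)
        g.ravel()[:7] = 1          # |g| = 7
        p.ravel()[:5] = 1          # 5 true positives
        p.ravel()[10:13] = 1       # 3 false positives; 2 false negatives remain
        c = confusion_counts(mask_from(p), mask_from(g))
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 54, 3, 2)
        assert specificity(c) == pytest.approx(54 / 57)
        assert sensitivity(c) == pytest.approx(5 / 7)
        assert auc_balanced(c) == pytest.approx(1 - 0.5 * (3 / 57 + 2 / 7))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridError):
            confusion_counts(mask_from(np.ones((3, 3, 3))),
                             mask_from(np.ones((4, 4, 4))))


class TestDice:
    def test_identical_masks(self, rng):
        m = mask_from((rng.random((6, 6, 6)) > 0.3).astype(np.uint8))
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0], b[2] = 1, 1
        assert dice(mask_from(a), mask_from(b)) == 0.0

    def test_hand_value_overlap_one_of_two(self):
        a = np.zeros((3, 3, 3), dtype=np.uint8)
        b = np.zeros((3, 3, 3), dtype=np.uint8)
        a.ravel()[[0, 1]] = 1
        b.ravel()[[1, 2]] = 1
        assert dice(mask_from(a), mask_from(b)) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = mask_from(np.zeros((3, 3, 3)))
        assert dice(z, z) == 1.0

    def test_squared_denominator_equals_cardinality_form(self, rng):
        p = (rng.random((8, 8, 8)) > 0.4).astype(np.uint8)
        g = (rng.random((8, 8, 8)) > 0.6).astype(np.uint8)
        c = confusion_counts(mask_from(p), mask_from(g))
        assert dice(mask_from(p), mask_from(g)) == pytest.approx(
            2 * c.tp / (2 * c.tp + c.fp + c.fn))


class TestOverlapCoefficient:
    def test_identical_masks_give_one(self, rng):
        m = mask_from((rng.random((6, 6, 6)) > 0.5).astype(np.uint8))
        assert overlap_coefficient(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0], b[3] = 1, 1
        assert overlap_coefficient(mask_from(a), mask_from(b)) == 0.0

    def test_subset_saturates(self):
        g = np.zeros((3, 3, 3), dtype=np.uint8)
        p = np.zeros((3, 3, 3), dtype=np.uint8)
        g.ravel()[:7] = 1
        p.ravel()[:3] = 1  # p ⊂ g
        assert overlap_coefficient(mask_from(p), mask_from(g)) == 1.0

    def test_empty_mask_rejected(self):
        z = mask_from(np.zeros((3, 3, 3)))
        o = mask_from(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            overlap_coefficient(z, o)


class TestRateErrors:
    def test_specificity_degenerate(self):
        with pytest.raises(ValueError):
            specificity(ConfusionCounts(tp=5, tn=0, fp=0, fn=2))

    def test_sensitivity_degenerate(self):
        with pytest.raises(ValueError):
            sensitivity(ConfusionCounts(tp=0, tn=5, fp=2, fn=0))

    def test_all_background_prediction_has_auc_half(self):
        g = np.zeros((4, 4, 4), dtype=np.uint8)
        g.ravel()[:10] = 1
        c = confusion_counts(mask_from(np.zeros_like(g)), mask_from(g))
        assert auc_balanced(c) == pytest.approx(0.5)


@settings(max_examples=200, derandomize=True)
@given(tp=st.integers(0, 1000), tn=st.integers(0, 1000),
       fp=st.integers(0, 1000), fn=st.integers(0, 1000))
def test_auc_is_mean_of_sensitivity_and_specificity(tp, tn, fp, fn):
    c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    if tp + fn == 0 or fp + tn == 0:
        with pytest.raises(ValueError):
            auc_balanced(c)
    else:
        assert auc_balanced(c) == pytest.approx(
            (sensitivity(c) + specificity(c)) / 2, abs=1e-15)


def test_oracle_equivalence_on_random_pairs():
    """All five measures match the voxel-loop oracle to 1e-12 on 100 random
    16³ mask pairs."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        density = rng.uniform(0.05, 0.95, size=2)
        p = (rng.random((16, 16, 16)) < density[0]).astype(np.uint8)
        g = (rng.random((16, 16, 16)) < density[1]).astype(np.uint8)
        ref = loop_oracle(p, g)
        if ref["OC"] is None or ref["SP"] is None or ref["SN"] is None:
            continue  # degenerate draws are exercised elsewhere
        rep = evaluate(mask_from(p), mask_from(g))
        got = rep.to_dict()
        for key in ("DSC", "OC", "SP", "SN", "AUC"):
            assert abs(got[key] - ref[key]) < 1e-12, key
        for key in ("TP", "TN", "FP", "FN"):
            assert got[key] == ref[key]
        assert all(0.0 <= got[k] <= 1.0 for k in ("DSC", "OC", "SP", "SN", "AUC"))
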