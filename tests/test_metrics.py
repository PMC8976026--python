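"""Dice and pixel-error metrics against a brute-force pixel-counting oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from adiposeg.core import LabelMap, SAT, VAT
from adiposeg.metrics import aggregate_group, dice, evaluate_examination, \
    pixel_error, volumetric_dice


def oracle_counts(R, P):
    """Naive per-pixel enumeration: intersection, sizes, disagreements."""
    inter = sizeR = sizeP = diff = 0
    for r, p in zip(R.ravel().tolist(), P.ravel().tolist()):
        sizeR += r
        sizeP += p
        inter += r and p
        diff += r != p
    return inter, sizeR, sizeP, diff


def oracle_dice(R, P):
    inter, sR, sP, _ = oracle_counts(R, P)
    return float("nan") if sR + sP == 0 else 2 * inter / (sR + sP)


def oracle_pixel_error(R, P):
    _, _, _, diff = oracle_counts(R, P)
    return 100.0 * diff / R.size


class TestDice:
    def test_identity(self):
        R = np.zeros((5, 5), bool)
        R[:2, :5] = True
        assert dice(R, R) == 1.0

    def test_disjoint_nonempty(self):
        R = np.zeros((4, 4), bool)
        P = np.zeros((4, 4), bool)
        R[0, 0] = True
        P[3, 3] = True
        assert dice(R, P) == 0.0

    def test_partial_overlap_matches_hand_count(self):
        R = np.zeros((4, 4), bool)
        P = np.zeros((4, 4), bool)
        R.ravel()[:4] = True          # |R| = 4
        P.ravel()[1:7] = True         # |P| = 6, |R∩P| = 3
        assert dice(R, P) == pytest.approx(0.6)

    def test_empty_vs_empty_flagged_nan(self):
        assert np.isnan(dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestPixelError:
    def test_identical_masks_zero(self):
        R = np.random.default_rng(0).random((8, 8)) > 0.5
        assert pixel_error(R, R) == 0.0

    def test_eight_disagreements_on_16x16(self):
        R = np.zeros((16, 16), bool)
        P = np.zeros((16, 16), bool)
        P.ravel()[:8] = True
        assert pixel_error(R, P) == pytest.approx(3.125)

    def test_maximal_disagreement(self):
        assert pixel_error(np.ones((4, 4), bool),
                           np.zeros((4, 4), bool)) == 100.0


class TestOracleEquivalence:
    @settings(max_examples=40, deadline=None)
    @given(arrays(bool, (9, 7)), arrays(bool, (9, 7)))
    def test_metrics_match_enumeration(self, R, P):
        if R.any() or P.any():
            assert dice(R, P) == pytest.approx(oracle_dice(R, P))
        assert pixel_error(R, P) == pytest.approx(oracle_pixel_error(R, P))

    @settings(max_examples=40, deadline=None)
    @given(arrays(bool, (8, 8)), arrays(bool, (8, 8)),
           st.integers(0, 63))
    def test_flip_monotonicity(self, R, P, flat_idx):
        """Flipping one agreeing pixel to disagree never helps either metric."""
        P = P.copy()
        P.ravel()[flat_idx] = R.ravel()[flat_idx]  # force agreement
        d0, e0 = dice(R, P), pixel_error(R, P)
        P.ravel()[flat_idx] = ~P.ravel()[flat_idx]  # now disagree
        d1, e1 = dice(R, P), pixel_error(R, P)
        if not (np.isnan(d0) or np.isnan(d1)):
            assert d1 <= d0 + 1e-12
        assert e1 >= e0 - 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            R = rng.random((12, 12)) > 0.6
            P = rng.random((12, 12)) > 0.6
            if R.any() or P.any():
                assert dice(R, P) == dice(P, R)
            assert pixel_error(R, P) == pixel_error(P, R)


class TestEvaluateExamination:
    @staticmethod
    def _lm(classes):
        return LabelMap(classes, spacing=(1, 1, 1))

    def test_perfect_prediction(self):
        rng = np.random.default_rng(1)
        m = self._lm(rng.integers(0, 3, (10, 10, 4)))
        out = evaluate_examination(m, m)
        for cls in ("SAT", "VAT"):
            assert all(d == 1.0 for d in out[cls]["dice"])
            assert all(e == 0.0 for e in out[cls]["pixel_error_pct"])

    def test_single_slice_equals_slice_metrics(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, (12, 12, 1))
        b = rng.integers(0, 3, (12, 12, 1))
        out = evaluate_examination(self._lm(a), self._lm(b))
        assert out["SAT"]["dice"][0] == pytest.approx(
            dice(a[:, :, 0] == SAT, b[:, :, 0] == SAT))
        assert out["VAT"]["pixel_error_pct"][0] == pytest.approx(
            pixel_error(a[:, :, 0] == VAT, b[:, :, 0] == VAT))

    def test_empty_empty_slices_excluded_by_default(self):
        a = np.zeros((6, 6, 3), int)
        b = np.zeros((6, 6, 3), int)
        a[2, 2, 0] = b[2, 2, 0] = SAT  # only slice 0 has SAT anywhere
        out = evaluate_examination(self._lm(a), self._lm(b))
        assert len(out["SAT"]["dice"]) == 1
        assert len(out["VAT"]["dice"]) == 0
        out1 = evaluate_examination(self._lm(a), self._lm(b),
                                    empty_policy="one")
        assert out1["VAT"]["dice"] == [1.0, 1.0, 1.0]

    def test_random_grids_match_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.integers(0, 3, (8, 8, 2))
            b = rng.integers(0, 3, (8, 8, 2))
            out = evaluate_examination(self._lm(a), self._lm(b),
                                       empty_policy="one")
            for cls, name in ((SAT, "SAT"), (VAT, "VAT")):
                for z in range(2):
                    od = oracle_dice(a[:, :, z] == cls, b[:, :, z] == cls)
                    if np.isnan(od):
                        od = 1.0
                    assert out[name]["dice"][z] == pytest.approx(od)
                    assert out[name]["pixel_error_pct"][z] == pytest.approx(
                        oracle_pixel_error(a[:, :, z] == cls,
                                           b[:, :, z] == cls))


class TestAggregateGroup:
    @staticmethod
    def _lm(classes):
        return LabelMap(classes, spacing=(1, 1, 1))

    def test_identical_masks_mean_one_sd_zero(self):
        rng = np.random.default_rng(4)
        m = self._lm(rng.integers(0, 3, (8, 8, 3)))
        rows = aggregate_group([evaluate_examination(m, m)], ["control"])
        for r in rows:
            assert r.dice_mean == 1.0
            assert r.dice_sd == 0.0

    def test_mean_across_examinations(self):
        e1 = {"SAT": {"dice": [1.0], "pixel_error_pct": [0.0]},
              "VAT": {"dice": [1.0], "pixel_error_pct": [0.0]}}
        e2 = {"SAT": {"dice": [0.5], "pixel_error_pct": [2.0]},
              "VAT": {"dice": [0.5], "pixel_error_pct": [2.0]}}
        rows = aggregate_group([e1, e2], ["g", "g"])
        sat = next(r for r in rows if r.compartment == "SAT")
        assert sat.dice_mean == pytest.approx(0.75)
        assert sat.n_slices == 2

    def test_row_count_is_groups_times_classes(self):
        rng = np.random.default_rng(6)
        exams = [evaluate_examination(self._lm(rng.integers(0, 3, (6, 6, 2))),
                                      self._lm(rng.integers(0, 3, (6, 6, 2))))
                 for _ in range(4)]
        rows = aggregate_group(exams, ["a", "a", "b", "b"])
        assert len(rows) == 4  # 2 groups × 2 compartments

    def test_volumetric_dice_secondary(self):
        rng = np.random.default_rng(7)
        a = self._lm(rng.integers(0, 3, (8, 8, 3)))
        assert volumetric_dice(a, a, SAT) == 1.0
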