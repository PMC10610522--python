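"""Heuristic overlap correction: decision rule, cut geometry, erosion and
the behavioural invariants on defective phantom maps."""

import numpy as np
import pytest

from echoseg.correct import (
    ChamberMask,
    CorrectionParams,
    TotalErasureError,
    apply_cut,
    correct_labelmap,
    erode_for_display,
    extract_chambers,
    extreme_distance,
    overlap_test,
)
from echoseg.metrics import dice


def _mask_with_extremes(class_id, top, bottom, shape=(128, 128)):
    """Minimal connected mask whose top/bottom extreme pixels are given
    as (x, y) points."""
    m = np.zeros(shape, bool)
    (x1, y1), (x2, y2) = top, bottom
    # vertical run at x1, a horizontal bridge one row above the bottom,
    # and a single bottom pixel at x2 — keeps both extremes as given
    m[y1 : max(y2, y1 + 1), x1] = True
    if y2 > y1:
        m[y2 - 1, min(x1, x2) : max(x1, x2) + 1] = True
    m[y2, x2] = True
    return ChamberMask.from_mask(class_id, m)


def _rect_mask(class_id, rows, cols, shape=(128, 128)):
    m = np.zeros(shape, bool)
    m[rows[0] : rows[1] + 1, cols[0] : cols[1] + 1] = True
    return ChamberMask.from_mask(class_id, m)


class TestExtractChambers:
    def test_largest_component_kept(self):
        lab = np.zeros((64, 64), np.uint8)
        lab[10:22, 10:20] = 3  # 120 px
        lab[40:41, 40:47] = 3  # 7 px satellite
        ch = extract_chambers(lab)
        assert ch[3].area == 120

    def test_clean_map_partitions_labels(self, default_frame_labels):
        _, labels = default_frame_labels
        ch = extract_chambers(labels)
        total = sum(c.area for c in ch.values())
        assert total == int((labels > 0).sum())
        assert set(ch) == {1, 2, 3, 4}

    def test_background_only_map(self):
        assert extract_chambers(np.zeros((32, 32), np.uint8)) == {}


class TestOverlap:
    def test_disjoint_extents(self):
        v = _rect_mask(3, (5, 40), (10, 30))
        a = _rect_mask(4, (50, 90), (10, 30))
        assert overlap_test(v, a) is False

    def test_overlapping_extents(self):
        v = _rect_mask(3, (5, 60), (10, 30))
        a = _rect_mask(4, (50, 90), (10, 30))
        assert overlap_test(v, a) is True

    def test_boundary_is_strict(self):
        v = _rect_mask(3, (5, 50), (10, 30))
        a = _rect_mask(4, (50, 90), (10, 30))
        assert overlap_test(v, a) is False

    def test_side_mismatch_raises(self):
        v = _rect_mask(1, (5, 40), (10, 30))
        a = _rect_mask(4, (50, 90), (10, 30))
        with pytest.raises(ValueError, match="side"):
            overlap_test(v, a)


class TestExtremeDistance:
    def test_worked_example(self):
        """Ventricle top (54, 9) vs atrium bottom (45, 80): sqrt(9^2+71^2)."""
        v = _mask_with_extremes(3, (54, 9), (60, 60))
        a = _mask_with_extremes(4, (50, 55), (45, 80))
        d = extreme_distance(v, a)
        assert d == pytest.approx(np.hypot(54 - 45, 9 - 80))
        assert round(d, 1) == 71.6

    def test_three_four_five(self):
        v = _mask_with_extremes(3, (0, 0), (0, 2))
        a = _mask_with_extremes(4, (0, 3), (3, 4))
        assert extreme_distance(v, a) == pytest.approx(5.0)

    def test_coincident_points(self):
        v = _mask_with_extremes(3, (10, 10), (10, 20))
        a = _mask_with_extremes(4, (10, 5), (10, 10))
        assert extreme_distance(v, a) == 0.0


class TestCut:
    def test_removes_rows_at_and_below_atrium_top(self):
        v = _rect_mask(3, (10, 55), (20, 40))
        a = _rect_mask(4, (50, 90), (20, 40))
        cut = apply_cut(v, a)
        assert cut.bottom[1] == 49
        np.testing.assert_array_equal(cut.mask[:50], v.mask[:50])
        assert not cut.mask[50:].any()
        assert cut.area < v.area

    def test_minimal_overlap(self):
        # one row strictly below the atrium top: the cut removes the rows
        # at and below that top row (two 21-px rows here), nothing else
        v = _rect_mask(3, (10, 51), (20, 40))
        a = _rect_mask(4, (50, 90), (20, 40))
        cut = apply_cut(v, a)
        assert v.area - cut.area == 2 * 21
        np.testing.assert_array_equal(cut.mask[:50], v.mask[:50])

    def test_total_erasure_raises(self):
        v = _rect_mask(3, (60, 70), (20, 40))
        a = _rect_mask(4, (50, 90), (20, 40))
        with pytest.raises(TotalErasureError):
            apply_cut(v, a)


class TestCorrectLabelmap:
    def test_clean_map_is_untouched(self, default_frame_labels):
        _, labels = default_frame_labels
        out, rep = correct_labelmap(labels)
        np.testing.assert_array_equal(out, labels)
        assert all(not s.cut_applied for s in rep.sides.values())
        assert all(s.pixels_removed == 0 for s in rep.sides.values())

    def test_long_overlap_triggers_cut(self):
        """An overlap whose extreme span exceeds the (rescaled) threshold
        is cut; the report carries distance and removed-pixel count."""
        lab = np.zeros((128, 128), np.uint8)
        lab[9:75, 40:60] = 3  # ventricle running far down
        lab[60:80, 38:39] = 0  # keep masks disjoint in columns
        lab[60:81, 20:38] = 4  # atrium top at row 60, bottom 80
        out, rep = correct_labelmap(lab)
        side = rep.sides["right"]
        assert side.overlap_detected and side.cut_applied
        assert side.distance > side.threshold == 68.5
        assert not (out[60:, :] == 3).any()
        assert side.pixels_removed == int((lab == 3).sum() - (out == 3).sum()) > 0

    def test_small_overlap_is_regular_anatomy(self):
        lab = np.zeros((128, 128), np.uint8)
        lab[30:65, 40:60] = 3
        lab[60:80, 20:38] = 4  # overlap rows 60-64 but span ~50 < 68.5
        out, rep = correct_labelmap(lab)
        side = rep.sides["right"]
        assert side.overlap_detected and not side.cut_applied
        np.testing.assert_array_equal(out, lab)

    def test_total_erasure_reported_not_raised(self):
        lab = np.zeros((128, 128), np.uint8)
        lab[100:126, 40:60] = 3  # ventricle entirely below atrium top
        lab[20:31, 20:38] = 4  # extreme span ~72 px exceeds the threshold
        out, rep = correct_labelmap(lab)
        assert rep.sides["right"].total_erasure
        np.testing.assert_array_equal(out, lab)

    def test_threshold_rescales_with_frame_diagonal(self):
        p = CorrectionParams()
        assert p.threshold_for("right", (128, 128)) == 68.5
        assert p.threshold_for("left", (128, 128)) == 76.5
        assert p.threshold_for("right", (112, 112)) == pytest.approx(68.5 * 112 / 128)

    def test_invariants_on_leaked_phantoms(self, leaked_maps):
        """Idempotence, per-class monotone area and left-side locality on
        defective maps (right-ventricle leaks)."""
        for clean, leaked in leaked_maps:
            out, rep = correct_labelmap(leaked)
            out2, _ = correct_labelmap(out)
            np.testing.assert_array_equal(out, out2)
            for c in (1, 2, 3, 4):
                assert (out == c).sum() <= (leaked == c).sum()
            for c in (1, 2):
                np.testing.assert_array_equal(out == c, leaked == c)


class TestErode:
    def test_zero_iterations_is_identity(self, default_frame_labels):
        _, labels = default_frame_labels
        params = CorrectionParams(erosion_iterations=0)
        np.testing.assert_array_equal(erode_for_display(labels, params), labels)

    def test_areas_non_increasing(self, default_frame_labels):
        _, labels = default_frame_labels
        out = erode_for_display(labels)
        for c in (1, 2, 3, 4):
            assert (out == c).sum() <= (labels == c).sum()
            assert (out == c).sum() > 0

    def test_congruent_squares_keep_area_ratio(self):
        lab = np.zeros((64, 64), np.uint8)
        lab[5:25, 5:25] = 1  # 20x20
        lab[30:50, 30:50] = 2  # 20x20
        out = erode_for_display(lab)
        assert (out == 1).sum() == (out == 2).sum() == 18 * 18
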