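import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import oracles
from hcha.core import (
    Block,
    CorrelationHistogram,
    RoiWindow,
    build_correlation_histogram,
    extract_roi,
    partition_layer1,
    partition_layer2,
    project_mask,
)
from hcha.errors import DimensionError, HchaError
from hcha.imaging_io import GrayImage

small_rois = hnp.arrays(
    np.uint8,
    hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=8),
    elements=st.integers(0, 12),
)


def _roi(arr):
    return RoiWindow(np.asarray(arr, dtype=np.uint8), (0, 0))


class TestExtractRoi:
    def test_256_center_window(self):
        img = GrayImage(np.arange(256 * 256).reshape(256, 256) % 256)
        roi = extract_roi(img, 50)
        assert roi.shape == (100, 100)
        assert roi.origin == (78, 78)
        assert np.array_equal(roi.pixels, img.pixels[78:178, 78:178])

    def test_exact_fit_is_identity(self, rng):
        img = GrayImage(rng.integers(0, 256, (100, 100)))
        roi = extract_roi(img, 50)
        assert roi.origin == (0, 0)
        assert np.array_equal(roi.pixels, img.pixels)

    def test_5x5_half_extent_1(self):
        img = GrayImage(np.arange(25).reshape(5, 5) * 10)
        roi = extract_roi(img, 1)
        assert roi.origin == (1, 1)
        assert np.array_equal(roi.pixels, img.pixels[1:3, 1:3])

    def test_too_small_raises(self):
        with pytest.raises(DimensionError):
            extract_roi(GrayImage(np.zeros((99, 120))), 50)

    def test_pixel_count(self, rng):
        img = GrayImage(rng.integers(0, 256, (30, 40)))
        assert extract_roi(img, 10).pixel_count == 400


class TestBuildHistogram:
    def test_constant_3x3_single_cell_40(self):
        hist = build_correlation_histogram(_roi(np.full((3, 3), 7)))
        assert hist.side == 1
        assert hist.offset == 7
        assert hist.counts[0, 0] == 40

    def test_degenerate_roi_raises(self):
        with pytest.raises(DimensionError):
            build_correlation_histogram(_roi(np.zeros((1, 5))))
        with pytest.raises(DimensionError):
            build_correlation_histogram(_roi(np.zeros((5, 1))))

    def test_random_4x4_matches_brute_force(self, rng):
        for _ in range(50):
            arr = rng.integers(0, 4, (4, 4))
            hist = build_correlation_histogram(_roi(arr))
            expected, lo = oracles.brute_histogram(arr)
            assert hist.offset == lo
            assert np.array_equal(hist.counts, expected)

    @pytest.mark.parametrize("m", [2, 3, 5, 12, 20])
    @pytest.mark.parametrize("n", [2, 4, 7, 20])
    def test_total_count_closed_form(self, rng, m, n):
        arr = rng.integers(0, 256, (m, n))
        hist = build_correlation_histogram(_roi(arr))
        assert hist.counts.sum() == 8 * m * n - 6 * (m + n) + 4

    @settings(max_examples=500, deadline=None)
    @given(arr=small_rois)
    def test_symmetry_property(self, arr):
        counts = build_correlation_histogram(_roi(arr)).counts
        assert np.array_equal(counts, counts.T)

    def test_side_spans_intensity_range(self):
        hist = build_correlation_histogram(_roi([[3, 9], [5, 3]]))
        assert hist.offset == 3
        assert hist.side == 7


class TestPartitions:
    @staticmethod
    def _hist(side):
        return CorrelationHistogram(np.zeros((side, side), dtype=np.int64), 0)

    def test_even_split(self):
        blocks = {b.label: b for b in partition_layer1(self._hist(8))}
        assert blocks["B2"].x_range == (0, 4) and blocks["B2"].y_range == (0, 4)
        assert blocks["B1"].x_range == (0, 4) and blocks["B1"].y_range == (4, 8)
        assert blocks["B3"].x_range == (4, 8) and blocks["B3"].y_range == (0, 4)
        assert blocks["B4"].x_range == (4, 8) and blocks["B4"].y_range == (4, 8)

    def test_odd_split_low_half_shorter(self):
        blocks = {b.label: b for b in partition_layer1(self._hist(5))}
        assert blocks["B2"].x_range == (0, 2)
        assert blocks["B4"].x_range == (2, 5)

    def test_single_cell_assigned_to_b2(self):
        blocks = {b.label: b for b in partition_layer1(self._hist(1))}
        assert blocks["B2"].x_range == (0, 1) and blocks["B2"].y_range == (0, 1)
        for label in ("B1", "B3", "B4"):
            assert blocks[label].is_empty

    def test_layer1_tiles_plane(self):
        for side in (1, 2, 3, 5, 8, 11, 256):
            cover = np.zeros((side, side), dtype=int)
            for b in partition_layer1(self._hist(side)):
                cover[b.x_range[0] : b.x_range[1], b.y_range[0] : b.y_range[1]] += 1
            assert np.all(cover == 1)

    def test_layer2_even(self):
        parent = Block("B2", (0, 4), (0, 4), 1)
        subs = {b.label: b for b in partition_layer2(parent)}
        assert subs["B22"].x_range == (0, 2) and subs["B22"].y_range == (0, 2)
        assert subs["B21"].x_range == (0, 2) and subs["B21"].y_range == (2, 4)
        assert subs["B23"].x_range == (2, 4) and subs["B23"].y_range == (0, 2)
        assert subs["B24"].x_range == (2, 4) and subs["B24"].y_range == (2, 4)
        assert all(b.layer == 2 for b in subs.values())

    def test_layer2_odd_midpoint(self):
        subs = {b.label: b for b in partition_layer2(Block("B4", (4, 9), (4, 9), 1))}
        assert subs["B42"].x_range == (4, 6)
        assert subs["B44"].x_range == (6, 9)

    def test_layer2_empty_parent(self):
        subs = partition_layer2(Block("B4", (3, 3), (3, 3), 1))
        assert len(subs) == 4
        assert all(b.is_empty for b in subs)

    def test_layer2_rejects_off_diagonal_parent(self):
        with pytest.raises(HchaError):
            partition_layer2(Block("B1", (0, 4), (4, 8), 1))

    def test_layer2_tiles_parent(self):
        parent = Block("B2", (2, 9), (2, 9), 1)
        cover = np.zeros((9, 9), dtype=int)
        for b in partition_layer2(parent):
            cover[b.x_range[0] : b.x_range[1], b.y_range[0] : b.y_range[1]] += 1
        assert np.all(cover[2:9, 2:9] == 1)
        assert cover.sum() == 49

    def test_layer2_nested_in_parent(self):
        parent = Block("B4", (5, 12), (5, 12), 1)
        for b in partition_layer2(parent):
            assert parent.x_range[0] <= b.x_range[0] <= b.x_range[1] <= parent.x_range[1]
            assert parent.y_range[0] <= b.y_range[0] <= b.y_range[1] <= parent.y_range[1]


class TestProjectMask:
    def test_constant_roi_all_in_b2(self):
        roi = _roi(np.full((4, 4), 9))
        hist = build_correlation_histogram(roi)
        blocks = {b.label: b for b in partition_layer1(hist)}
        assert np.all(project_mask(roi, hist, blocks["B2"]).mask == 1)
        for label in ("B1", "B3", "B4"):
            assert np.all(project_mask(roi, hist, blocks[label]).mask == 0)

    def test_two_level_roi_b1_marks_boundary(self):
        # left half value 0 (low), right half value 3 (high)
        arr = np.array([[0, 0, 3, 3]] * 4)
        roi = _roi(arr)
        hist = build_correlation_histogram(roi)
        blocks = {b.label: b for b in partition_layer1(hist)}
        mask = project_mask(roi, hist, blocks["B1"]).mask
        expected = np.zeros((4, 4), dtype=np.uint8)
        expected[:, 1] = 1  # only low-valued pixels touching the high half
        assert np.array_equal(mask, expected)

    def test_diagonal_masks_disjoint(self, rng):
        for _ in range(20):
            roi = _roi(rng.integers(0, 10, (6, 6)))
            hist = build_correlation_histogram(roi)
            blocks = {b.label: b for b in partition_layer1(hist)}
            m2 = project_mask(roi, hist, blocks["B2"]).mask
            m4 = project_mask(roi, hist, blocks["B4"]).mask
            assert not np.any(m2 & m4)

    def test_out_of_plane_block_rejected(self):
        roi = _roi(np.zeros((3, 3)))
        hist = build_correlation_histogram(roi)
        with pytest.raises(HchaError):
            project_mask(roi, hist, Block("B4", (0, 5), (0, 1), 1))

    def test_matches_brute_force_all_blocks(self, rng):
        for _ in range(30):
            arr = rng.integers(0, 5, tuple(rng.integers(2, 7, 2)))
            roi = _roi(arr)
            hist = build_correlation_histogram(roi)
            layer1 = {b.label: b for b in partition_layer1(hist)}
            blocks = list(layer1.values())
            for parent in ("B2", "B4"):
                blocks += partition_layer2(layer1[parent])
            for block in blocks:
                got = project_mask(roi, hist, block).mask
                want = oracles.brute_mask(arr, hist.offset, block.x_range, block.y_range, hist.counts)
                assert np.array_equal(got, want), block.label

    @settings(max_examples=100, deadline=None)
    @given(arr=small_rois)
    def test_masks_match_brute_force_property(self, arr):
        roi = _roi(arr)
        hist = build_correlation_histogram(roi)
        for block in partition_layer1(hist):
            got = project_mask(roi, hist, block).mask
            want = oracles.brute_mask(arr, hist.offset, block.x_range, block.y_range, hist.counts)
            assert np.array_equal(got, want)
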