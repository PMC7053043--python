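"""Core density pipeline: ROI median, threshold, masks, percent density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammodens import (
    MammogramImage,
    RoiSpec,
    View,
    compute_dense_mask,
    compute_percent_density,
    compute_roi_median,
    compute_threshold,
    make_overlay,
    measure,
    segment_background,
)
from mammodens.density import aggregate_subject

from .conftest import brute_force_background


def _mlo(values):
    return MammogramImage(pixels=np.asarray(values, dtype=float), view=View.MLO)


def _cc(values):
    return MammogramImage(pixels=np.asarray(values, dtype=float), view=View.CC)


class TestRoiMedian:
    @pytest.mark.parametrize(
        "values, roi, expected",
        [
            ([[5, 7, 9]], RoiSpec(0, 1, 0, 3), 7.0),  # odd count
            ([[4, 8]], RoiSpec(0, 1, 0, 2), 6.0),  # even count: mean of middles
            ([[100, 100], [100, 100]], RoiSpec(0, 2, 0, 2), 100.0),  # constant
        ],
    )
    def test_median_conventions(self, values, roi, expected):
        assert compute_roi_median(_mlo(values), roi) == expected

    def test_out_of_bounds_roi(self):
        with pytest.raises(ValueError, match="bounds"):
            compute_roi_median(_mlo([[1, 2], [3, 4]]), RoiSpec(0, 3, 0, 2))

    def test_wrong_view(self):
        with pytest.raises(ValueError, match="MLO"):
            compute_roi_median(_cc([[1, 2]]), RoiSpec(0, 1, 0, 2))

    def test_zero_pixels_included(self):
        # all ROI pixels contribute, background zeros included
        assert compute_roi_median(_mlo([[0, 0, 9]]), RoiSpec(0, 1, 0, 3)) == 0.0


class TestThreshold:
    @pytest.mark.parametrize(
        "median, constant, expected",
        [(100.0, 0.72, 72.0), (37.5, 1.0, 37.5), (0.0, 0.72, 0.0)],
    )
    def test_multiplication(self, median, constant, expected):
        assert compute_threshold(median, constant) == expected

    def test_nonpositive_constant(self):
        with pytest.raises(ValueError):
            compute_threshold(100.0, 0.0)


class TestBackground:
    def test_all_zero_grid(self):
        assert segment_background(_cc(np.zeros((5, 5)))).n_breast == 0

    def test_single_nonzero_center(self):
        px = np.zeros((5, 5))
        px[2, 2] = 7
        breast = segment_background(_cc(px))
        # the nonzero pixel plus its 8 zero neighbours are breast
        assert breast.n_breast == 9
        assert breast.mask[1:4, 1:4].all()

    def test_no_zero_pixels(self):
        breast = segment_background(_cc(np.ones((4, 6))))
        assert breast.n_breast == 24

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(2, 9),
        st.integers(2, 9),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_rule(self, rows, cols, seed):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 3, size=(rows, cols)).astype(float)
        px[px == 1] = 0  # sprinkle extra zeros
        breast = segment_background(_cc(px))
        assert np.array_equal(breast.mask, ~brute_force_background(px))

    def test_component_mode_keeps_interior_holes(self):
        px = np.ones((7, 7)) * 50
        px[3, 3] = 0  # isolated zero hole inside tissue
        px[:, 0] = 0  # border background column
        literal = segment_background(_cc(px), mode="literal")
        comp = segment_background(_cc(px), mode="component")
        assert comp.mask[3, 3]  # hole survives in component mode
        assert literal.mask[3, 3]  # single hole also survives the literal rule
        # border zeros adjacent to tissue count as breast under the literal rule
        assert literal.n_breast >= comp.n_breast


class TestDenseMask:
    def test_threshold_is_inclusive(self):
        px = np.array([[10.0, 72.0, 80.0]])
        img = _cc(px)
        breast = segment_background(img)
        dense = compute_dense_mask(img, breast, 72.0)
        assert dense.tolist() == [[False, True, True]]

    def test_threshold_above_max(self, small_cc):
        breast = segment_background(small_cc)
        assert not compute_dense_mask(small_cc, breast, 1e9).any()

    def test_nonpositive_threshold_rejected(self, small_cc):
        breast = segment_background(small_cc)
        with pytest.raises(ValueError):
            compute_dense_mask(small_cc, breast, 0.0)

    def test_phantom_truth_recovered(self, clean_phantom):
        p = clean_phantom
        threshold = p.spec.muscle_intensity * p.spec.muscle_gland_ratio
        breast = segment_background(p.cc)
        dense = compute_dense_mask(p.cc, breast, threshold)
        assert np.array_equal(dense, p.dense_mask_truth)


class TestPercentDensity:
    def _breast(self, n, total=1000):
        px = np.zeros((1, total + 2))
        px[0, 1 : total + 1] = 10.0
        img = _cc(px)
        breast = segment_background(img)
        dense = np.zeros_like(px, dtype=bool)
        dense[0, 1 : n + 1] = True
        return breast, dense

    def test_direct_ratio(self):
        breast, dense = self._breast(250)
        percent, reported = compute_percent_density(breast, dense)
        assert percent == 100 * 250 / breast.n_breast
        assert reported == round(percent)

    def test_clamp_to_one(self):
        breast, dense = self._breast(1)
        percent, reported = compute_percent_density(breast, dense)
        assert 0 < percent < 0.5
        assert reported == 1

    def test_zero_dense(self):
        breast, dense = self._breast(0)
        assert compute_percent_density(breast, dense) == (0.0, 0)

    def test_empty_breast_signalled(self):
        img = _cc(np.zeros((3, 3)))
        breast = segment_background(img)
        with pytest.raises(ValueError, match="no breast"):
            compute_percent_density(breast, np.zeros((3, 3), dtype=bool))

    def test_half_rounds_away_from_zero(self):
        # 3 dense of 8 breast pixels → 37.5% → reported 38 (half away from 0)
        px = np.zeros((1, 8))
        px[0, 1:7] = 10.0
        img = _cc(px)
        breast = segment_background(img)
        assert breast.n_breast == 8  # 6 tissue + 2 rim zeros
        dense = np.zeros_like(px, dtype=bool)
        dense[0, 1:4] = True
        percent, reported = compute_percent_density(breast, dense)
        assert percent == 37.5
        assert reported == 38


class TestOverlay:
    def test_all_false_reproduces_grayscale(self, small_cc):
        rgb = make_overlay(small_cc, np.zeros(small_cc.shape, dtype=bool))
        assert rgb.shape == (*small_cc.shape, 3)
        assert (rgb[:, :, 0] == rgb[:, :, 1]).all() and (rgb[:, :, 1] == rgb[:, :, 2]).all()
        assert np.array_equal(rgb[:, :, 0], small_cc.pixels.astype(np.uint8))

    def test_tinted_count_equals_dense_count(self, clean_phantom):
        p = clean_phantom
        rgb = make_overlay(p.cc, p.dense_mask_truth, color=(255, 0, 0))
        tinted = (rgb[:, :, 0] == 255) & (rgb[:, :, 1] == 0) & (rgb[:, :, 2] == 0)
        assert tinted.sum() == p.dense_mask_truth.sum()


class TestMeasure:
    def test_scale_invariance(self, clean_phantom):
        p = clean_phantom
        base = measure(p.mlo, p.cc, p.roi)
        for k in (0.25, 3.0):
            scaled = measure(
                MammogramImage(p.mlo.pixels * k, View.MLO),
                MammogramImage(p.cc.pixels * k, View.CC),
                p.roi,
            )
            assert scaled.percent_density == base.percent_density

    def test_monotone_in_constant(self, clean_phantom):
        p = clean_phantom
        counts = [
            measure(p.mlo, p.cc, p.roi, constant=c).n_dense
            for c in (0.3, 0.5, 0.72, 0.9, 1.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_roi_on_background_rejected(self, clean_phantom):
        p = clean_phantom
        rows, cols = p.mlo.shape
        corner = RoiSpec(rows - 4, rows - 1, cols - 4, cols - 1)  # background corner
        with pytest.raises(ValueError, match="background"):
            measure(p.mlo, p.cc, corner)

    def test_view_contracts(self, clean_phantom):
        p = clean_phantom
        with pytest.raises(ValueError):
            measure(p.cc, p.cc, p.roi)
        with pytest.raises(ValueError):
            measure(p.mlo, p.mlo, p.roi)

    def test_deterministic(self, clean_phantom):
        p = clean_phantom
        r1 = measure(p.mlo, p.cc, p.roi)
        r2 = measure(p.mlo, p.cc, p.roi)
        assert r1.to_dict() == r2.to_dict()
        assert np.array_equal(r1.dense_mask, r2.dense_mask)

    def test_naive_recount_oracle(self):
        # full pipeline counts equal a per-pixel double-loop recount
        rng = np.random.default_rng(42)
        px = np.zeros((32, 32))
        blob = rng.integers(20, 200, size=(20, 20)).astype(float)
        px[6:26, 0:20] = blob
        cc = _cc(px)
        mlo_px = px.copy()
        mlo_px[0:8, 0:8] = 150.0
        mlo = _mlo(mlo_px)
        roi = RoiSpec(0, 8, 0, 8)
        res = measure(mlo, cc, roi)
        bg = brute_force_background(px)
        n_breast = 0
        n_dense = 0
        for r in range(32):
            for c in range(32):
                if not bg[r, c]:
                    n_breast += 1
                    if px[r, c] >= res.threshold:
                        n_dense += 1
        assert res.n_breast == n_breast
        assert res.n_dense == n_dense


def test_subject_aggregation_is_mean():
    assert aggregate_subject([20.0, 30.0]) == 25.0
    with pytest.raises(ValueError):
        aggregate_subject([])
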