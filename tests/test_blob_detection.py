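"""Segmentation and feature extraction: examples, oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toxid.blob_detection import (
    DegenerateBlobError,
    GrayFrame,
    extract_detection,
    hu_moments,
    normalize_roi,
    roi_histogram,
    segment_frame,
)


def frame_of(pixels, index=0):
    return GrayFrame(np.asarray(pixels, dtype=np.float64), index)


def block_frame(value=0.0, bg=255.0, shape=(100, 100), rows=(20, 30), cols=(20, 30)):
    px = np.full(shape, bg)
    px[rows[0] : rows[1], cols[0] : cols[1]] = value
    return frame_of(px)


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentFrame:
    def test_blank_frame_has_no_blobs(self):
        assert segment_frame(frame_of(np.full((20, 20), 255.0)), 100, 1, 10_000) == []

    def test_single_block(self):
        blobs = segment_frame(block_frame(), 100, 10, 10_000)
        assert len(blobs) == 1
        assert blobs[0].size == 100
        assert blobs[0].bbox == (20, 20, 29, 29)

    def test_size_filter_drops_isolated_pixel(self):
        px = np.full((30, 30), 255.0)
        px[2:5, 2:5] = 0      # 9 px
        px[10:13, 20:23] = 0  # 9 px
        px[25, 25] = 0        # isolated
        blobs = segment_frame(frame_of(px), 100, 5, 10_000)
        assert len(blobs) == 2

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            segment_frame(block_frame(), 300, 1, 10)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            GrayFrame(np.empty((0, 0)), 0)

    def test_matches_floodfill_oracle(self):
        """Components equal a brute-force 8-connected flood fill on random
        binary frames, in count and in membership."""

        def flood_components(mask, min_size):
            seen = np.zeros_like(mask, dtype=bool)
            comps = []
            h, w = mask.shape
            for r0 in range(h):
                for c0 in range(w):
                    if not mask[r0, c0] or seen[r0, c0]:
                        continue
                    stack, comp = [(r0, c0)], set()
                    seen[r0, c0] = True
                    while stack:
                        r, c = stack.pop()
                        comp.add((r, c))
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                rr, cc = r + dr, c + dc
                                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
                    if len(comp) >= min_size:
                        comps.append(frozenset(comp))
            return set(comps)

        rng = np.random.default_rng(7)
        for _ in range(50):
            mask = rng.random((64, 64)) < 0.25
            frame = frame_of(np.where(mask, 0.0, 255.0))
            blobs = segment_frame(frame, 128, 3, 10_000)
            expected = flood_components(mask, 3)
            got = {frozenset(b.pixel_set) for b in blobs}
            assert got == expected

    def test_deterministic_order(self):
        px = np.full((40, 40), 255.0)
        px[30:34, 2:6] = 0
        px[2:6, 30:34] = 0
        blobs = segment_frame(frame_of(px), 100, 4, 100)
        assert blobs[0].bbox[0] == 2  # row-major first pixel ordering


# ---------------------------------------------------------------------------
# ROI normalisation and histogram


class TestNormalizeRoi:
    def test_endpoints_stretched(self):
        fr = frame_of([[10, 10], [110, 210]])
        roi = normalize_roi(fr, (0, 0, 1, 1))
        assert roi[0, 0] == 0.0 and roi[1, 1] == 255.0

    def test_constant_roi_maps_to_zero(self):
        fr = frame_of(np.full((5, 5), 37.0))
        assert not normalize_roi(fr, (0, 0, 4, 4)).any()

    def test_full_range_unchanged(self):
        vals = np.linspace(0, 255, 16).reshape(4, 4).round()
        vals[0, 0], vals[-1, -1] = 0, 255
        roi = normalize_roi(frame_of(vals), (0, 0, 3, 3))
        np.testing.assert_allclose(roi, vals)

    def test_bbox_outside_frame(self):
        with pytest.raises(ValueError):
            normalize_roi(frame_of(np.zeros((5, 5))), (0, 0, 5, 5))


class TestRoiHistogram:
    def test_all_zero_roi(self):
        hist = roi_histogram(np.zeros((4, 4)), 8)
        assert hist[0] == 16 and hist[1:].sum() == 0

    def test_top_edge_goes_to_last_bin(self):
        hist = roi_histogram(np.array([[255.0]]), 8)
        assert hist[-1] == 1 and hist.sum() == 1

    def test_uniform_ramp(self):
        hist = roi_histogram(np.arange(256, dtype=float).reshape(16, 16), 4)
        np.testing.assert_array_equal(hist, [64, 64, 64, 64])

    def test_kn_too_small(self):
        with pytest.raises(ValueError):
            roi_histogram(np.zeros((2, 2)), 1)

    @settings(deadline=None, max_examples=40)
    @given(
        st.integers(2, 64),
        st.integers(1, 12),
        st.integers(1, 12),
        st.integers(0, 2**31 - 1),
    )
    def test_mass_conservation(self, kn, h, w, seed):
        roi = np.random.default_rng(seed).uniform(0, 255, (h, w))
        assert roi_histogram(roi, kn).sum() == h * w


# ---------------------------------------------------------------------------
# Hu invariants


def _blob_and_roi(pixels, threshold=210):
    fr = frame_of(pixels)
    blobs = segment_frame(fr, threshold, 5, 1_000_000)
    assert len(blobs) == 1
    return normalize_roi(fr, blobs[0].bbox), blobs[0]


def _random_blob_frame(rng):
    px = np.full((60, 60), 255.0)
    h, w = rng.integers(8, 20, 2)
    r0, c0 = rng.integers(5, 30, 2)
    px[r0 : r0 + h, c0 : c0 + w] = rng.uniform(0, 200, (h, w)).round()
    return px


class TestHuMoments:
    def test_rotation_and_translation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            px = _random_blob_frame(rng)
            hu = hu_moments(*_blob_and_roi(px))
            for k in (1, 2):  # exact 90 and 180 degree grid rotations
                hu_rot = hu_moments(*_blob_and_roi(np.rot90(px, k).copy()))
                np.testing.assert_allclose(hu_rot, hu, rtol=1e-6)
            shifted = np.full((80, 80), 255.0)
            shifted[5:65, 7:67] = px
            hu_shift = hu_moments(*_blob_and_roi(shifted))
            np.testing.assert_allclose(hu_shift, hu, rtol=1e-9)

    def test_mirror_flips_seventh_invariant_only(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            px = _random_blob_frame(rng)
            hu = hu_moments(*_blob_and_roi(px))
            hu_m = hu_moments(*_blob_and_roi(px[:, ::-1].copy()))
            np.testing.assert_allclose(hu_m[:6], hu[:6], rtol=1e-6)
            np.testing.assert_allclose(abs(hu_m[6]), abs(hu[6]), rtol=1e-6)

    def test_upscaling_invariance(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            px = _random_blob_frame(rng)
            hu = hu_moments(*_blob_and_roi(px))
            big = np.kron(px, np.ones((2, 2)))
            hu_big = hu_moments(*_blob_and_roi(big))
            np.testing.assert_allclose(hu_big, hu, rtol=5e-2)

    def test_disc_vs_elongated_ellipse(self):
        """Equal-area shapes with different elongation separate on the first
        invariant; checked against a raw central-moment oracle."""

        def oracle_hu1(mask):
            rows, cols = np.nonzero(mask)
            m00 = rows.size
            rbar, cbar = rows.mean(), cols.mean()
            mu20 = ((cols - cbar) ** 2).sum()
            mu02 = ((rows - rbar) ** 2).sum()
            return (mu20 + mu02) / m00**2

        yy, xx = np.mgrid[0:101, 0:101]
        disc = (xx - 50) ** 2 + (yy - 50) ** 2 <= 15**2
        # 3:1 ellipse of (nearly) equal area: a*b = 15**2
        a, b = 15 * np.sqrt(3), 15 / np.sqrt(3)
        ellipse = ((xx - 50) / a) ** 2 + ((yy - 50) / b) ** 2 <= 1

        h_disc, h_ell = oracle_hu1(disc), oracle_hu1(ellipse)
        assert abs(h_disc - h_ell) / h_disc > 0.10

        def impl_hu(mask):
            px = np.where(mask, 0.0, 255.0)
            roi, blob = _blob_and_roi(px)
            return hu_moments(roi, blob, binary=True)

        np.testing.assert_allclose(impl_hu(disc)[0], h_disc, rtol=1e-9)
        np.testing.assert_allclose(impl_hu(ellipse)[0], h_ell, rtol=1e-9)
        assert abs(impl_hu(disc)[0] - impl_hu(ellipse)[0]) / impl_hu(disc)[0] > 0.10

    def test_degenerate_blob_rejected(self):
        fr = frame_of(np.full((6, 6), 37.0))
        px = np.full((10, 10), 255.0)
        px[2:5, 2:5] = 37.0
        blobs = segment_frame(frame_of(px), 100, 5, 100)
        roi = normalize_roi(frame_of(np.full((10, 10), 37.0)), blobs[0].bbox)
        with pytest.raises(DegenerateBlobError):
            hu_moments(roi, blobs[0])


# ---------------------------------------------------------------------------
# detection assembly


class TestExtractDetection:
    def test_block_centroid_and_size(self):
        fr = block_frame()
        blob = segment_frame(fr, 100, 10, 10_000)[0]
        det = extract_detection(fr, blob, fps=25.0, kn=8)
        assert det.cm == (24.5, 24.5)
        assert det.size == 100
        assert det.hist.sum() == 100  # 10x10 ROI

    def test_single_pixel_blob(self):
        px = np.full((20, 20), 255.0)
        px[5, 9] = 0
        fr = frame_of(px)
        blob = segment_frame(fr, 100, 1, 100)[0]
        det = extract_detection(fr, blob, fps=25.0, kn=8)
        assert det.cm == (9.0, 5.0) and det.size == 1

    def test_time_base(self):
        fr = block_frame()
        fr = GrayFrame(fr.pixels, 60)
        blob = segment_frame(fr, 100, 10, 10_000)[0]
        assert extract_detection(fr, blob, fps=30.0, kn=8).t == 2.0

    def test_centroid_inside_bbox(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            fr = frame_of(_random_blob_frame(rng))
            for blob in segment_frame(fr, 210, 5, 10_000):
                det = extract_detection(fr, blob, fps=25.0, kn=8)
                r0, c0, r1, c1 = det.bbox
                assert c0 <= det.cm[0] <= c1 and r0 <= det.cm[1] <= r1
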