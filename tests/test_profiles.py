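"""Normalization, profile extraction and spot counting contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from filotip import count_myo10_spots, extract_profile, find_maxima, normalize_image
from filotip.errors import ArgumentError, ConstantImageError, EmptyMaskError


def _gauss_spot(shape, cy, cx, amp, sigma=1.5):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


class TestNormalizeImage:
    def test_full_range_image_is_unchanged(self):
        img = np.zeros((10, 10), dtype=np.uint16)
        img[5, 5] = 65535
        mask = np.zeros((10, 10), bool)
        mask[4:7, 4:7] = True
        np.testing.assert_array_equal(normalize_image(img, mask), img)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        ref = (rng.integers(0, 30000, (20, 20)) * 2).astype(np.uint16)  # even values
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        ref[~mask] = 100  # constant background floor
        half = (ref // 2).astype(np.uint16)
        np.testing.assert_array_equal(
            normalize_image(ref, mask), normalize_image(half, mask)
        )

    def test_direct_formula_oracle(self):
        img = np.full((12, 12), 500, dtype=np.uint16)  # background mode 500
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        img[4, 4] = 10500  # in-mask max
        img[5, 5] = 5500
        out = normalize_image(img, mask)
        expected = np.clip(
            np.round((img.astype(float) - 500) * 65535 / 10000), 0, 65535
        )
        np.testing.assert_array_equal(out, expected.astype(np.uint16))

    def test_constant_image_raises(self):
        img = np.full((8, 8), 7, dtype=np.uint16)
        with pytest.raises(ConstantImageError):
            normalize_image(img, np.ones((8, 8), bool))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            normalize_image(np.zeros((4, 4), np.uint16), np.zeros((4, 4), bool))


class TestExtractProfile:
    def test_constant_image(self):
        img = np.full((20, 20), 1234.0)
        rec = extract_profile(img, [[2, 3], [15, 3]], pixel_size=0.1)
        np.testing.assert_allclose(rec.intensities, 1234.0)

    def test_horizontal_line_equals_raw_pixels(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 65535, (10, 30)).astype(float)
        rec = extract_profile(img, [[3, 5], [23, 5]], pixel_size=0.08)
        np.testing.assert_allclose(rec.intensities, img[5, 3:24])
        assert rec.arc_positions_um[0] == 0.0
        assert rec.length_um == pytest.approx(20 * 0.08)

    def test_diagonal_gradient_matches_bilinear_closed_form(self):
        # bilinear interpolation reproduces an affine image exactly
        yy, xx = np.mgrid[0:40, 0:40]
        img = 2.0 * xx + 3.0 * yy
        rec = extract_profile(img, [[5, 7], [25, 31]], pixel_size=0.1)
        total = np.hypot(20, 24)
        ts = rec.arc_positions_um / 0.1 / total
        expected = 2.0 * (5 + ts * 20) + 3.0 * (7 + ts * 24)
        np.testing.assert_allclose(rec.intensities, expected, rtol=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        img = rng.random((30, 30)) * 1000
        shifted = np.zeros((36, 36))
        shifted[4:34, 6:36] = img
        a = extract_profile(img, [[3, 4], [20, 18]], pixel_size=0.1)
        b = extract_profile(shifted, [[9, 8], [26, 22]], pixel_size=0.1)
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-9)

    def test_too_short_polyline_raises(self):
        with pytest.raises(ArgumentError, match="shorter than 2"):
            extract_profile(np.zeros((10, 10)), [[1, 1], [1.5, 1]], pixel_size=0.1)


def _persistence_maxima_count(image: np.ndarray, prominence: float) -> int:
    """Brute-force oracle: count maxima with topographic persistence >= h.

    Pixels are flooded in descending order with union-find; when a pixel
    merges components, every component except the one with the highest peak
    dies with persistence (peak - current level).  Surviving components
    persist down to the image minimum.  Requires all-distinct pixel values.
    """
    img = image.astype(float)
    order = np.argsort(img.ravel())[::-1]
    h, w = img.shape
    parent = {}
    peak = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    count = 0
    for flat in order:
        r, c = divmod(int(flat), w)
        neigh_roots = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (dr or dc) and 0 <= rr < h and 0 <= cc < w and (rr, cc) in parent:
                    neigh_roots.add(find((rr, cc)))
        parent[(r, c)] = (r, c)
        if not neigh_roots:
            peak[(r, c)] = img[r, c]
            continue
        roots = sorted(neigh_roots, key=lambda rt: peak[rt], reverse=True)
        winner = roots[0]
        parent[(r, c)] = winner
        for loser in roots[1:]:
            if peak[loser] - img[r, c] >= prominence:
                count += 1
            parent[loser] = winner
    # survivors die at the global minimum
    lo = img.min()
    for rt in {find(k) for k in parent}:
        if peak[rt] - lo >= prominence:
            count += 1
    return count


class TestFindMaxima:
    def test_blank_image_has_no_maxima(self):
        assert len(find_maxima(np.zeros((10, 10), dtype=np.int64), 10)) == 0

    def test_ridge_saddle_semantics(self):
        img = np.zeros((20, 20), dtype=np.int64)
        img[5, 5] = 1000
        img[5, 15] = 1000
        img[5, 6:15] = 920  # both peaks drop 80 to the joining saddle
        assert len(find_maxima(img, 80)) == 2   # inclusive: drop >= prominence
        assert len(find_maxima(img, 81)) == 1
        assert len(find_maxima(img, 30)) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("prominence", [50, 200, 1000])
    def test_counts_match_persistence_oracle(self, seed, prominence):
        rng = np.random.default_rng(seed)
        # distinct values avoid plateau ties, where persistence is ambiguous
        img = rng.permutation(12 * 12).reshape(12, 12).astype(np.int64) * 20
        assert len(find_maxima(img, prominence)) == _persistence_maxima_count(
            img, prominence
        )


class TestCountSpots:
    def _field(self):
        factin = np.zeros((80, 80))
        factin[20:60, 20:60] = 15000  # the cell body
        myo10 = np.zeros((80, 80))
        outside = [(10, 10), (70, 12), (8, 65)]
        inside = [(30, 30), (45, 50)]
        for cy, cx in outside + inside:
            myo10 += _gauss_spot((80, 80), cy, cx, amp=20000)
        return np.round(myo10).astype(np.int64), factin, len(outside)

    def test_blank_images_raise_on_empty_mask(self):
        with pytest.raises(EmptyMaskError):
            count_myo10_spots(
                np.zeros((20, 20)), np.zeros((20, 20)), prominence=100,
                mask_threshold=10, background_radius=None,
            )

    def test_counts_only_spots_outside_cell_mask(self):
        myo10, factin, k = self._field()
        assert count_myo10_spots(
            myo10, factin, prominence=2000, background_radius=None
        ) == k

    def test_count_increases_with_extra_outside_spot(self):
        myo10, factin, k = self._field()
        myo10 = myo10 + np.round(_gauss_spot((80, 80), 70, 70, 20000)).astype(np.int64)
        assert count_myo10_spots(
            myo10, factin, prominence=2000, background_radius=None
        ) == k + 1

    def test_background_subtraction_path(self):
        myo10, factin, k = self._field()
        ramp = (np.linspace(0, 300, 80)[None, :] * np.ones((80, 1))).astype(np.int64)
        assert count_myo10_spots(
            myo10 + ramp, factin, prominence=2000, background_radius=10.0
        ) == k


class TestSpotInvariance:
    @given(st.integers(0, 3))
    def test_spots_inside_mask_never_change_count(self, n_inside):
        factin = np.zeros((60, 60))
        factin[15:45, 15:45] = 15000
        myo10 = _gauss_spot((60, 60), 8, 8, 20000)
        rng = np.random.default_rng(n_inside)
        for _ in range(n_inside):
            cy, cx = rng.integers(20, 40, 2)
            myo10 = myo10 + _gauss_spot((60, 60), cy, cx, 20000)
        count = count_myo10_spots(
            np.round(myo10).astype(np.int64), factin,
            prominence=2000, background_radius=None,
        )
        assert count == 1
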