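"""CLAHE building blocks, reduction properties, and the per-pixel oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctenhance.enhance import (
    CLAHE,
    EnhanceParams,
    apply_clahe,
    apply_gaussian,
    apply_he,
    clip_histogram,
    tile_cdf,
    tile_histogram,
)
from ctenhance.exceptions import DegenerateTileError


# ---------------------------------------------------------------- oracle
def clahe_oracle(image, clip_fraction, tile_size, levels=256):
    """Independent per-pixel CLAHE: recomputes the four neighboring tile
    mappings for every pixel and blends them with explicit bilinear weights.
    Deliberately naive and loop-based."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    pad_h = (-h) % tile_size
    pad_w = (-w) % tile_size
    padded = np.pad(image, ((0, pad_h), (0, pad_w)), mode="reflect")
    ph, pw = padded.shape
    n_tr, n_tc = ph // tile_size, pw // tile_size
    n_pix = tile_size * tile_size
    cap = max(1, int(np.floor(abs(clip_fraction * n_pix) + 0.5)))

    def mapping_for(r, c):
        tile = padded[r * tile_size:(r + 1) * tile_size,
                      c * tile_size:(c + 1) * tile_size]
        hist = np.zeros(levels)
        for v in tile.ravel():
            b = min(int(v * levels), levels - 1)
            hist[b] += 1
        clipped = np.minimum(hist, cap)
        clipped = clipped + (hist.sum() - clipped.sum()) / levels
        cdf = np.cumsum(clipped) / n_pix
        return cdf / cdf[-1]

    maps = {}
    out = np.empty_like(padded)
    for y in range(ph):
        for x in range(pw):
            rf = (y + 0.5) / tile_size - 0.5
            cf = (x + 0.5) / tile_size - 0.5
            r0, c0 = int(np.floor(rf)), int(np.floor(cf))
            tr, tc = rf - r0, cf - c0
            b = min(int(padded[y, x] * levels), levels - 1)
            acc = 0.0
            for dr, wr in ((r0, 1 - tr), (r0 + 1, tr)):
                for dc, wc in ((c0, 1 - tc), (c0 + 1, tc)):
                    rr = min(max(dr, 0), n_tr - 1)
                    cc = min(max(dc, 0), n_tc - 1)
                    if (rr, cc) not in maps:
                        maps[(rr, cc)] = mapping_for(rr, cc)
                    acc += wr * wc * maps[(rr, cc)][b]
            out[y, x] = acc
    return np.clip(out[:h, :w], 0.0, 1.0)


# ---------------------------------------------------------- histogram steps
class TestTileHistogram:
    def test_four_even_bins(self):
        tile = np.array([[0.0, 1 / 3], [2 / 3, 1.0]])
        assert tile_histogram(tile, levels=4).tolist() == [1, 1, 1, 1]

    def test_constant_tile_single_bin(self):
        hist = tile_histogram(np.full((3, 3), 0.5), levels=8)
        assert hist.sum() == 9 and hist[4] == 9

    def test_top_value_in_top_bin(self):
        hist = tile_histogram(np.ones((2, 2)), levels=10)
        assert hist[-1] == 4

    def test_counts_conserved(self, rng):
        tile = rng.random((16, 16))
        assert tile_histogram(tile, levels=256).sum() == 256


class TestClipHistogram:
    def test_literal_truncation(self):
        out = clip_histogram([5, 3, 0, 2], clip_fraction=0.3, tile_pixels=10,
                             mode="literal")
        assert out.tolist() == [3, 3, 0, 2]

    def test_redistribute_conserves_mass(self):
        out = clip_histogram([5, 3, 0, 2], clip_fraction=0.3, tile_pixels=10)
        assert out.tolist() == [3.5, 3.5, 0.5, 2.5]
        assert out.sum() == pytest.approx(10)

    @pytest.mark.parametrize("mode", ["literal", "redistribute"])
    def test_no_clipping_when_cap_large(self, mode):
        hist = [4, 1, 3, 2]
        out = clip_histogram(hist, clip_fraction=0.5, tile_pixels=10, mode=mode)
        assert out.tolist() == hist

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError, match="tile_pixels"):
            clip_histogram([1, 2], clip_fraction=0.1, tile_pixels=10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_redistribution_conserves_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 40, size=32).astype(float)
        hist[0] += 1  # non-empty
        n = hist.sum()
        out = clip_histogram(hist, clip_fraction=0.05, tile_pixels=n)
        assert abs(out.sum() - n) < 1e-9 * n


class TestTileCdf:
    def test_uniform_counts(self):
        out = tile_cdf([1, 1, 1, 1], tile_pixels=4)
        assert out.tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_renormalized_after_literal_clip(self):
        raw = tile_cdf([3, 3, 0, 2], tile_pixels=10, renormalize=False)
        np.testing.assert_allclose(raw, [0.3, 0.6, 0.6, 0.8])
        out = tile_cdf([3, 3, 0, 2], tile_pixels=10)
        np.testing.assert_allclose(out, [0.375, 0.75, 0.75, 1.0])

    def test_single_occupied_bin_maps_to_one(self):
        out = tile_cdf([0, 0, 7, 0], tile_pixels=7)
        assert out[2] == 1.0 and out[-1] == 1.0

    def test_degenerate_tile(self):
        with pytest.raises(DegenerateTileError):
            tile_cdf([0, 0, 0], tile_pixels=4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mapping_monotone(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 9, size=16).astype(float)
        counts[rng.integers(0, 16)] += 1
        out = tile_cdf(counts, tile_pixels=counts.sum())
        assert (np.diff(out) >= 0).all() and out[-1] == 1.0


# ------------------------------------------------------------- apply_clahe
class TestApplyClahe:
    def test_single_tile_full_clip_reduces_to_he(self, rng):
        img = rng.random((8, 8))
        clahe = apply_clahe(img, EnhanceParams(clip_fraction=1.0, tile_size=8))
        he = apply_he(img)
        np.testing.assert_array_equal(clahe, he)

    def test_output_contract(self, rng):
        img = rng.random((37, 53))  # non-divisible edges exercise padding
        out = apply_clahe(img, EnhanceParams(clip_fraction=0.05, tile_size=16))
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_matches_per_pixel_oracle(self, rng):
        img = rng.random((64, 64))
        out = apply_clahe(img, EnhanceParams(clip_fraction=0.05, tile_size=16))
        ref = clahe_oracle(img, 0.05, 16)
        np.testing.assert_allclose(out, ref, atol=1e-9)

    def test_deterministic(self, rng):
        img = rng.random((32, 32))
        p = EnhanceParams(clip_fraction=0.1, tile_size=8)
        np.testing.assert_array_equal(apply_clahe(img, p), apply_clahe(img, p))

    def test_single_tile_preserves_rank_order(self, rng):
        img = rng.random((16, 16))
        out = apply_clahe(img, EnhanceParams(clip_fraction=0.2, tile_size=16))
        order_in = np.argsort(img.ravel(), kind="stable")
        assert (np.diff(out.ravel()[order_in]) >= -1e-12).all()

    def test_oversized_tile_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller tile"):
            apply_clahe(rng.random((8, 8)), EnhanceParams(0.1, 64))

    def test_stack_transform(self, rng):
        stack = rng.random((3, 16, 16))
        out = CLAHE(clip_fraction=0.1, tile_size=8).transform(stack)
        assert out.shape == stack.shape

    def test_sklearn_params_roundtrip(self):
        est = CLAHE(clip_fraction=0.2, tile_size=32)
        assert CLAHE(**est.get_params()).get_params() == est.get_params()


# ------------------------------------------------------------------- he
class TestHistogramEqualization:
    def test_four_pixel_cdf(self):
        img = np.array([[0.0, 1 / 3], [2 / 3, 1.0]])
        np.testing.assert_allclose(
            apply_he(img, levels=4), [[0.25, 0.5], [0.75, 1.0]]
        )

    def test_constant_image_maps_to_one(self):
        np.testing.assert_array_equal(
            apply_he(np.full((4, 4), 0.3)), np.ones((4, 4))
        )

    def test_uniform_histogram_stays_uniform(self, rng):
        levels = 16
        vals = (np.arange(levels) + 0.5) / levels
        img = rng.permutation(np.repeat(vals, 4)).reshape(8, 8)
        out = apply_he(img, levels=levels)
        # equalizing an exactly flat histogram keeps one pixel per level
        assert len(np.unique(out)) == levels


# -------------------------------------------------------------- gaussian
class TestGaussianSmoothing:
    def test_constant_fixed_point(self):
        img = np.full((9, 9), 0.4)
        np.testing.assert_allclose(apply_gaussian(img, sigma=2.0), img)

    def test_impulse_mass_conserved(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        assert apply_gaussian(img, sigma=1.0).sum() == pytest.approx(1.0)

    def test_matches_dense_convolution_oracle(self):
        img = np.zeros((21, 21))
        img[:, 11:] = 1.0  # step edge
        out = apply_gaussian(img, sigma=1.0)
        # dense separable-kernel oracle with explicit reflect padding
        radius = int(4.0 * 1.0 + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-(x**2) / 2.0)
        k /= k.sum()
        padded = np.pad(img, radius, mode="reflect")
        ref = np.empty_like(img)
        for i in range(21):
            for j in range(21):
                win = padded[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
                ref[i, j] = k @ win @ k
        np.testing.assert_allclose(out, ref, atol=1e-9)
        assert (np.diff(out[10]) >= -1e-12).all()  # monotone transition

    def test_nonpositive_sigma_rejected(self, rng):
        with pytest.raises(ValueError, match="sigma"):
            apply_gaussian(rng.random((8, 8)), sigma=0.0)
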