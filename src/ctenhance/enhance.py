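"""Contrast enhancement operators on 2-D patches.

All operators work on grayscale images with intensities in the closed unit
interval [0, 1] (the working range produced by :mod:`ctenhance.ct_io` when a
Hounsfield window is applied).  Three methods are provided:

* CLAHE — contrast-limited adaptive histogram equalization, built from its
  defining per-tile histogram / clip / CDF steps with bilinear blending of
  tile mappings.  This is the method whose two parameters (clip limit C,
  tile size T) the :class:`~ctenhance.optimize.CLAHETuner` searches over.
* Global histogram equalization (HE), the conventional baseline.
* Gaussian smoothing, a representative denoising baseline.

Each method is exposed both as a scikit-learn style transformer (``CLAHE``,
``HistogramEqualizer``, ``GaussianSmoother``) operating on a single image or
a stack of images, and as a plain function (``apply_clahe``, ``apply_he``,
``apply_gaussian``) wrapping the transformer.

Intensity quantization uses ``levels`` equal-width bins over [0, 1]; a value
``v`` falls in bin ``floor(v * levels)`` clamped to ``levels - 1`` so that
1.0 belongs to the top bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateTileError

__all__ = [
    "EnhanceParams",
    "CLAHE",
    "HistogramEqualizer",
    "GaussianSmoother",
    "tile_histogram",
    "clip_histogram",
    "tile_cdf",
    "apply_clahe",
    "apply_he",
    "apply_gaussian",
    "save_image_png",
    "load_image_png",
]


@dataclass(frozen=True)
class EnhanceParams:
    """The CLAHE parameter pair theta = (clip limit C, tile size T).

    clip_fraction : float
        C, the per-bin cap expressed as a fraction of the tile pixel count
        N = T*T; the absolute cap is ``max(1, round(C * N))``.
    tile_size : int
        T, tile edge length in pixels.
    mode : str
        ``"redistribute"`` (clip then spread the excess uniformly over all
        bins, conserving mass) or ``"literal"`` (truncation only, mass lost).
    """

    clip_fraction: float
    tile_size: int
    mode: str = "redistribute"

    def __post_init__(self):
        if self.tile_size < 2:
            raise ValueError(f"tile_size must be >= 2, got {self.tile_size}")
        if not 0 < self.clip_fraction <= 1.0:
            raise ValueError(
                f"clip_fraction must lie in (0, 1], got {self.clip_fraction}"
            )
        if self.mode not in ("redistribute", "literal"):
            raise ValueError(f"unknown clip mode {self.mode!r}")


def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _bin_index(values: np.ndarray, levels: int) -> np.ndarray:
    idx = np.floor(np.asarray(values, dtype=float) * levels).astype(np.int64)
    return np.clip(idx, 0, levels - 1)


def _validate_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("image values must lie in [0, 1]")
    return arr


def _pad_to_multiple(image: np.ndarray, tile: int) -> np.ndarray:
    """Reflect-pad on the bottom/right so both edges divide by ``tile``."""
    out = image
    for axis in (0, 1):
        want = (-out.shape[axis]) % tile
        while want > 0:
            step = min(want, out.shape[axis] - 1)
            pad = [(0, 0), (0, 0)]
            if step == 0:  # degenerate 1-pixel edge: repeat it
                pad[axis] = (0, want)
                out = np.pad(out, pad, mode="edge")
                break
            pad[axis] = (0, step)
            out = np.pad(out, pad, mode="reflect")
            want -= step
    return out


def tile_histogram(tile, levels: int = 256) -> np.ndarray:
    """Per-bin counts of a tile over ``levels`` equal-width bins on [0, 1]."""
    tile = _validate_image(tile)
    idx = _bin_index(tile, levels)
    return np.bincount(idx.ravel(), minlength=levels).astype(float)


def clip_histogram(
    hist,
    clip_fraction: float,
    tile_pixels: int,
    mode: str = "redistribute",
) -> np.ndarray:
    """Cap each bin at ``max(1, round(clip_fraction * tile_pixels))``.

    In ``redistribute`` mode the clipped excess is spread uniformly over all
    bins in a single pass so total mass is conserved (bins may then slightly
    exceed the cap); in ``literal`` mode the truncated histogram is returned
    as-is and the excess mass is lost.
    """
    hist = np.asarray(hist, dtype=float)
    if abs(hist.sum() - tile_pixels) > 1e-6 * max(1.0, tile_pixels):
        raise ValueError(
            f"histogram sums to {hist.sum()}, expected tile_pixels={tile_pixels}"
        )
    c_abs = max(1.0, float(_round_half_away(clip_fraction * tile_pixels)))
    clipped = np.minimum(hist, c_abs)
    if mode == "literal":
        return clipped
    if mode != "redistribute":
        raise ValueError(f"unknown clip mode {mode!r}")
    excess = hist.sum() - clipped.sum()
    return clipped + excess / hist.size


def tile_cdf(clipped, tile_pixels: int, renormalize: bool = True) -> np.ndarray:
    """Cumulative mapping of a (clipped) tile histogram.

    The raw CDF divides the running sum by the tile pixel count N.  By
    default the mapping is then renormalized by its final value so the top
    occupied bin maps to exactly 1.0 (without renormalization a literal
    clip compresses the output range; that behavior is available with
    ``renormalize=False`` for fidelity checks).
    """
    clipped = np.asarray(clipped, dtype=float)
    if np.any(clipped < 0):
        raise ValueError("histogram counts must be non-negative")
    cdf = np.cumsum(clipped) / float(tile_pixels)
    if cdf[-1] <= 0:
        raise DegenerateTileError("tile histogram carries no mass")
    if renormalize:
        return cdf / cdf[-1]
    return cdf


class CLAHE(TransformerMixin, BaseEstimator):
    """Contrast-limited adaptive histogram equalization.

    The image is reflect-padded to a multiple of the tile size, a clipped
    histogram and cumulative mapping are built for every T x T tile, and
    each pixel's output is the bilinear blend of the four nearest tile-center
    mappings evaluated at the pixel's intensity bin (pixels beyond the
    outermost tile centers fall back to two mappings on edges and one in
    corners).  The padding is cropped, so output shape equals input shape.

    Parameters
    ----------
    clip_fraction : float, default 0.1
        Clip limit C as a fraction of the tile pixel count.
    tile_size : int, default 16
        Tile edge length T in pixels.
    levels : int, default 256
        Number of quantization bins L.
    mode : {"redistribute", "literal"}, default "redistribute"
        How clipped excess mass is handled.
    renormalize : bool, default True
        Renormalize each tile mapping so its top value is 1.0.
    """

    def __init__(
        self,
        clip_fraction: float = 0.1,
        tile_size: int = 16,
        levels: int = 256,
        mode: str = "redistribute",
        renormalize: bool = True,
    ):
        self.clip_fraction = clip_fraction
        self.tile_size = tile_size
        self.levels = levels
        self.mode = mode
        self.renormalize = renormalize

    def _params(self) -> EnhanceParams:
        return EnhanceParams(
            clip_fraction=self.clip_fraction,
            tile_size=int(self.tile_size),
            mode=self.mode,
        )

    def fit(self, X, y=None):
        self._params()  # validates
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        return self

    def transform(self, X):
        self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return self._transform_one(X)
        if X.ndim == 3:
            return np.stack([self._transform_one(img) for img in X])
        raise ValueError("expected a 2-D image or a stack of 2-D images")

    def _transform_one(self, image: np.ndarray) -> np.ndarray:
        image = _validate_image(image)
        T = int(self.tile_size)
        h, w = image.shape
        if T > 4 * max(h, w):
            raise ValueError(
                f"tile_size {T} exceeds 4x the image edge ({h}x{w}); "
                "use a smaller tile"
            )
        levels = int(self.levels)
        padded = _pad_to_multiple(image, T)
        ph, pw = padded.shape
        n_tr, n_tc = ph // T, pw // T
        n_pix = T * T

        bins_all = _bin_index(padded, levels)
        tile_bins = bins_all.reshape(n_tr, T, n_tc, T).swapaxes(1, 2)

        mappings = np.empty((n_tr, n_tc, levels), dtype=float)
        for r in range(n_tr):
            for c in range(n_tc):
                hist = np.bincount(
                    tile_bins[r, c].ravel(), minlength=levels
                ).astype(float)
                clipped = clip_histogram(
                    hist, self.clip_fraction, n_pix, mode=self.mode
                )
                mappings[r, c] = tile_cdf(
                    clipped, n_pix, renormalize=self.renormalize
                )

        # fractional tile coordinates of every pixel relative to tile centers
        rf = (np.arange(ph) + 0.5) / T - 0.5
        cf = (np.arange(pw) + 0.5) / T - 0.5
        r0 = np.floor(rf).astype(int)
        c0 = np.floor(cf).astype(int)
        tr = rf - r0
        tc = cf - c0
        r0c = np.clip(r0, 0, n_tr - 1)
        r1c = np.clip(r0 + 1, 0, n_tr - 1)
        c0c = np.clip(c0, 0, n_tc - 1)
        c1c = np.clip(c0 + 1, 0, n_tc - 1)

        R0 = r0c[:, None]
        R1 = r1c[:, None]
        C0 = c0c[None, :]
        C1 = c1c[None, :]
        wr = tr[:, None]
        wc = tc[None, :]
        out = (
            (1 - wr) * (1 - wc) * mappings[R0, C0, bins_all]
            + (1 - wr) * wc * mappings[R0, C1, bins_all]
            + wr * (1 - wc) * mappings[R1, C0, bins_all]
            + wr * wc * mappings[R1, C1, bins_all]
        )
        return np.clip(out[:h, :w], 0.0, 1.0)


class HistogramEqualizer(TransformerMixin, BaseEstimator):
    """Global histogram equalization over ``levels`` bins.

    The mapping is the image CDF renormalized to end at 1.0; a constant
    image therefore maps to the constant 1.0 (the occupied bin's CDF is 1).
    """

    def __init__(self, levels: int = 256):
        self.levels = levels

    def fit(self, X, y=None):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        return self

    def transform(self, X):
        self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return self._transform_one(X)
        if X.ndim == 3:
            return np.stack([self._transform_one(img) for img in X])
        raise ValueError("expected a 2-D image or a stack of 2-D images")

    def _transform_one(self, image: np.ndarray) -> np.ndarray:
        image = _validate_image(image)
        levels = int(self.levels)
        hist = tile_histogram(image, levels)
        mapping = tile_cdf(hist, image.size, renormalize=True)
        return mapping[_bin_index(image, levels)]


class GaussianSmoother(TransformerMixin, BaseEstimator):
    """2-D Gaussian smoothing with reflect boundaries, truncated at 4 sigma."""

    def __init__(self, sigma: float = 1.0):
        self.sigma = sigma

    def fit(self, X, y=None):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        return self

    def transform(self, X):
        self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return self._transform_one(X)
        if X.ndim == 3:
            return np.stack([self._transform_one(img) for img in X])
        raise ValueError("expected a 2-D image or a stack of 2-D images")

    def _transform_one(self, image: np.ndarray) -> np.ndarray:
        image = _validate_image(image)
        return ndimage.gaussian_filter(
            image, sigma=self.sigma, mode="reflect", truncate=4.0
        )


def apply_clahe(image, params: EnhanceParams, levels: int = 256,
                renormalize: bool = True) -> np.ndarray:
    """Apply CLAHE with the given (C, T) parameters to one image."""
    est = CLAHE(
        clip_fraction=params.clip_fraction,
        tile_size=params.tile_size,
        levels=levels,
        mode=params.mode,
        renormalize=renormalize,
    )
    return est.transform(image)


def apply_he(image, levels: int = 256) -> np.ndarray:
    """Global histogram equalization of one image."""
    return HistogramEqualizer(levels=levels).transform(image)


def apply_gaussian(image, sigma: float) -> np.ndarray:
    """Gaussian smoothing of one image."""
    return GaussianSmoother(sigma=sigma).transform(image)


def save_image_png(image, path) -> None:
    """Write a [0, 1] image as a 16-bit grayscale PNG."""
    import imageio.v3 as iio

    arr = _validate_image(image)
    iio.imwrite(str(path), np.round(arr * 65535.0).astype(np.uint16))


def load_image_png(path) -> np.ndarray:
    """Read a 16-bit grayscale PNG back onto the [0, 1] working range."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)), dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a grayscale PNG, got shape {arr.shape}")
    return arr / 65535.0
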