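"""Image-quality metrics and the composite enhancement objective.

The fidelity of an enhanced patch is always judged against the original
(un-enhanced) patch:

* MSE — mean squared pixel difference.
* PSNR — 10*log10(MAX_I^2 / MSE) in dB; +inf for identical images (capped
  only inside the composite objective so the identity enhancement stays
  comparable).
* NRMSE — sqrt(MSE) normalized by the intensity range (max - min) of the
  reference image.
* SSIM — the standard windowed structural similarity (11x11 Gaussian
  window, sigma 1.5, C1=(0.01 L)^2, C2=(0.03 L)^2, population moments)
  averaged over all fully interior window positions; images smaller than
  the window fall back to a single global window.

The composite objective combines them as

    f(theta) = alpha * min(PSNR, cap) + beta * SSIM - gamma * NRMSE

which rewards fidelity and structural preservation while penalizing
distortion; ``evaluate_params`` averages f over a calibration set for one
CLAHE parameter pair and is the quantity the CMA-ES tuner maximizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .enhance import EnhanceParams, apply_clahe
from .exceptions import EmptyRegionError

__all__ = [
    "QualityReport",
    "ObjectiveConfig",
    "mse",
    "psnr",
    "nrmse",
    "ssim",
    "composite_objective",
    "evaluate_params",
    "quality_report",
]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Weights and conventions of the composite objective.

    alpha, beta, gamma : non-negative weights on PSNR, SSIM and NRMSE.
        Defaults are 1/1/1; note PSNR's dB scale then dominates, consistent
        with the best parameters also maximizing PSNR.
    psnr_cap : dB value substituted for +inf when MSE = 0.
    max_val : MAX_I / dynamic range L of the working intensity scale.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    psnr_cap: float = 100.0
    max_val: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("objective weights must be non-negative")
        if max(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("at least one objective weight must be positive")
        if not np.isfinite(self.psnr_cap):
            raise ValueError("psnr_cap must be finite")


@dataclass(frozen=True)
class QualityReport:
    """Metric bundle for one (original, enhanced) pair."""

    psnr: float
    ssim: float
    mse: float
    nrmse: float
    composite: float


def _pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    """Mean squared pixel difference."""
    a, b = _pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are equal."""
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    err = mse(a, b)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / err))


def nrmse(a, b) -> float:
    """Root-mean-square error normalized by the reference image a's range."""
    a, b = _pair(a, b)
    span = float(a.max() - a.min())
    if span == 0:
        raise EmptyRegionError("reference image is constant; NRMSE undefined")
    return float(np.sqrt(mse(a, b)) / span)


def _gaussian_kernel(win_size: int, sigma: float) -> np.ndarray:
    r = np.arange(win_size) - (win_size - 1) / 2.0
    k = np.exp(-(r**2) / (2.0 * sigma**2))
    k /= k.sum()
    return np.outer(k, k)


def ssim(a, b, max_val: float = 1.0, win_size: int = 11,
         sigma: float = 1.5) -> float:
    """Mean structural similarity between two images.

    Windowed Gaussian-weighted SSIM over all interior window positions;
    images with an edge shorter than ``win_size`` use a single uniform
    global window instead.
    """
    a, b = _pair(a, b)
    c1 = (0.01 * max_val) ** 2
    c2 = (0.03 * max_val) ** 2
    if min(a.shape) < win_size:
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(), b.var()
        cov = float(np.mean((a - mu_a) * (b - mu_b)))
        num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
        den = (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
        return float(num / den)

    kern = _gaussian_kernel(win_size, sigma)

    def f(x):
        return signal.correlate(x, kern, mode="valid", method="direct")

    mu_a = f(a)
    mu_b = f(b)
    va = f(a * a) - mu_a**2
    vb = f(b * b) - mu_b**2
    cov = f(a * b) - mu_a * mu_b
    smap = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    )
    return float(smap.mean())


def composite_objective(original, enhanced,
                        config: ObjectiveConfig = ObjectiveConfig()) -> float:
    """alpha * min(PSNR, cap) + beta * SSIM - gamma * NRMSE, enhanced vs original."""
    p = min(psnr(original, enhanced, max_val=config.max_val), config.psnr_cap)
    s = ssim(original, enhanced, max_val=config.max_val)
    n = nrmse(original, enhanced)
    return float(config.alpha * p + config.beta * s - config.gamma * n)


def quality_report(original, enhanced,
                   config: ObjectiveConfig = ObjectiveConfig()) -> QualityReport:
    """All four metrics plus the composite value for one image pair."""
    m = mse(original, enhanced)
    p = psnr(original, enhanced, max_val=config.max_val)
    s = ssim(original, enhanced, max_val=config.max_val)
    n = nrmse(original, enhanced)
    comp = config.alpha * min(p, config.psnr_cap) + config.beta * s - config.gamma * n
    return QualityReport(psnr=p, ssim=s, mse=m, nrmse=n, composite=float(comp))


def evaluate_params(images, params: EnhanceParams,
                    config: ObjectiveConfig = ObjectiveConfig(),
                    levels: int = 256) -> float:
    """Mean composite objective of CLAHE(params) over a calibration set."""
    images = list(images)
    if not images:
        raise ValueError("calibration set must be non-empty")
    total = 0.0
    for img in images:
        enhanced = apply_clahe(img, params, levels=levels)
        total += composite_objective(img, enhanced, config)
    return total / len(images)
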