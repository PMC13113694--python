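"""CutMix augmentation for 2-D training patches.

A rectangular region of one image is replaced by the corresponding region
of a partner image and the labels are mixed by the kept-area fraction:

    x~ = M * xA + (1 - M) * xB
    y~ = lam * yA + (1 - lam) * yB,   lam = area(M) / (H * W)

where the binary mask M marks pixels kept from xA.  The target fraction is
drawn from Beta(alpha, alpha) and the cut rectangle has side ratio
sqrt(1 - lam); after border clipping the realized lam is recomputed from
the actual mask, so the area identity holds exactly for every draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MixedSample",
    "sample_lambda",
    "make_mask",
    "cutmix_pair",
    "cutmix_batch",
]


@dataclass(frozen=True)
class MixedSample:
    """One augmented image with its soft label and realized mix fraction."""

    image: np.ndarray
    label: float
    lam: float
    mask: np.ndarray


def sample_lambda(alpha: float, rng: np.random.Generator) -> float:
    """One draw from Beta(alpha, alpha); alpha=1 gives a uniform fraction."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return float(rng.beta(alpha, alpha))


def make_mask(height: int, width: int, lam_target: float,
              rng: np.random.Generator):
    """Binary keep-mask with a uniformly placed cut rectangle.

    The rectangle (where the partner image is pasted, mask value 0) has
    height H*sqrt(1-lam) and width W*sqrt(1-lam), rounded; its center is
    drawn uniformly and then shifted just enough to keep the whole
    rectangle inside the image, so a full-size cut covers the image
    exactly.  Returns ``(mask, lam_realized)`` with ``lam_realized``
    recomputed from the actual mask so the area identity is exact.
    """
    if height < 1 or width < 1:
        raise ValueError("mask dimensions must be >= 1")
    if not 0.0 <= lam_target <= 1.0:
        raise ValueError(f"lam_target must lie in [0, 1], got {lam_target}")
    ratio = np.sqrt(1.0 - lam_target)
    cut_h = int(np.round(height * ratio))
    cut_w = int(np.round(width * ratio))
    mask = np.ones((height, width), dtype=np.uint8)
    if cut_h > 0 and cut_w > 0:
        cy = int(rng.integers(0, height))
        cx = int(rng.integers(0, width))
        y0 = int(np.clip(cy - cut_h // 2, 0, height - cut_h))
        x0 = int(np.clip(cx - cut_w // 2, 0, width - cut_w))
        mask[y0:y0 + cut_h, x0:x0 + cut_w] = 0
    lam_realized = float(mask.sum()) / float(height * width)
    return mask, lam_realized


def cutmix_pair(x_a, y_a: float, x_b, y_b: float, alpha: float,
                rng: np.random.Generator) -> MixedSample:
    """Mix two labeled images into one augmented sample."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape:
        raise ValueError(f"shape mismatch: {x_a.shape} vs {x_b.shape}")
    if not (0.0 <= y_a <= 1.0 and 0.0 <= y_b <= 1.0):
        raise ValueError("labels must lie in [0, 1]")
    lam_target = sample_lambda(alpha, rng)
    mask, lam = make_mask(x_a.shape[0], x_a.shape[1], lam_target, rng)
    mixed = np.where(mask == 1, x_a, x_b)
    label = lam * y_a + (1.0 - lam) * y_b
    return MixedSample(image=mixed, label=float(label), lam=lam, mask=mask)


def cutmix_batch(images, labels, alpha: float = 1.0, seed: int = 0):
    """Mix every batch element with a randomly chosen partner.

    Returns ``(mixed_images, soft_labels)`` as arrays; deterministic for a
    fixed seed, suitable for streaming into a training loop.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if images.ndim != 3 or len(labels) != len(images):
        raise ValueError("expected a (n, H, W) batch with matching labels")
    rng = np.random.default_rng(seed)
    partners = rng.integers(0, len(images), size=len(images))
    mixed = np.empty_like(images)
    soft = np.empty(len(images), dtype=float)
    for i, j in enumerate(partners):
        sample = cutmix_pair(
            images[i], float(labels[i]), images[j], float(labels[j]),
            alpha, rng,
        )
        mixed[i] = sample.image
        soft[i] = sample.label
    return mixed, soft
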