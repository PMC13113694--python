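"""Average lung intensity and low/medium/high scan stratification.

Scanner and protocol differences shift the apparent brightness of lung
parenchyma between CT scans.  To quantify this, the mean Hounsfield value
I_avg = (1/N) * sum(P_i) is computed over a lung mask of N voxels, and
scans are grouped into low-, medium- and high-intensity categories by two
HU cutoffs (explicit, or the empirical tercile boundaries of the supplied
means).

The lung mask is a deliberately simple, deterministic heuristic validated
on phantoms: voxels in the parenchymal band (-950, -300) HU, closed with a
radius-2 structuring element, holes filled, restricted to the (at most
two) largest connected components that do not touch the array border.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology, segmentation

from .exceptions import EmptyRegionError

__all__ = [
    "IntensityProfile",
    "lung_mask",
    "mean_lung_intensity",
    "stratify",
    "profiles_to_csv",
]

HU_BAND = (-950.0, -300.0)


@dataclass(frozen=True)
class IntensityProfile:
    """Per-scan summary: mean HU over the lung mask and the assigned group."""

    series_id: str
    mean_hu: float
    n_pixels: int
    group: str = "unassigned"


def lung_mask(hu_array) -> np.ndarray:
    """Heuristic lung-parenchyma mask of a 2-D slice or 3-D volume in HU.

    May be empty (e.g. when the only thresholded component touches the
    border, as for an unbounded uniform region).
    """
    arr = np.asarray(hu_array, dtype=float)
    if arr.ndim not in (2, 3):
        raise ValueError("expected a 2-D slice or 3-D volume")
    band = (arr > HU_BAND[0]) & (arr < HU_BAND[1])
    if not band.any():
        return np.zeros_like(band)
    footprint = morphology.ball(2) if arr.ndim == 3 else morphology.disk(2)
    closed = morphology.closing(band, footprint).astype(bool)
    filled = ndimage.binary_fill_holes(closed)
    interior = segmentation.clear_border(filled)
    labels, n = ndimage.label(interior)
    if n == 0:
        return np.zeros_like(band)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    return np.isin(labels, keep)


def mean_lung_intensity(image, mask) -> float:
    """Arithmetic mean HU over the masked voxels (I_avg)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise EmptyRegionError("mask is empty; mean intensity undefined")
    return float(image[mask].mean())


def stratify(profiles, thresholds=None) -> list[IntensityProfile]:
    """Assign each profile to the low / medium / high intensity group.

    With explicit ``thresholds = (t1, t2)`` (t1 < t2): low if mean < t1,
    high if mean >= t2, medium otherwise.  When omitted, t1 and t2 are the
    empirical 1/3 and 2/3 quantiles (linear interpolation) of the supplied
    means, which requires at least 3 profiles.
    """
    profiles = list(profiles)
    if thresholds is None:
        if len(profiles) < 3:
            raise ValueError("auto thresholds require at least 3 profiles")
        means = np.array([p.mean_hu for p in profiles])
        t1, t2 = np.quantile(means, [1.0 / 3.0, 2.0 / 3.0])
    else:
        t1, t2 = thresholds
        if t1 >= t2:
            raise ValueError(f"thresholds must satisfy t1 < t2, got {t1} >= {t2}")
    out = []
    for p in profiles:
        if p.mean_hu < t1:
            group = "low"
        elif p.mean_hu >= t2:
            group = "high"
        else:
            group = "medium"
        out.append(replace(p, group=group))
    return out


def profiles_to_csv(profiles, path) -> None:
    """Export profiles as CSV with columns series_id, mean_hu, n_pixels, group."""
    pd.DataFrame(
        [
            {
                "series_id": p.series_id,
                "mean_hu": p.mean_hu,
                "n_pixels": p.n_pixels,
                "group": p.group,
            }
            for p in profiles
        ],
        columns=["series_id", "mean_hu", "n_pixels", "group"],
    ).to_csv(path, index=False)
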