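"""MetaImage CT volumes, candidate tables, and patch extraction.

Conventions (stated at every interface):

* Voxel arrays are ordered (z, y, x); spacing, origin and direction
  metadata are ordered (x, y, z) as in the MetaImage header.
* Only diagonal direction matrices with +/-1 entries are supported; any
  other orientation raises :class:`~ctenhance.exceptions.FormatError`
  instead of silently misplacing candidates.
* Candidate tables use the LUNA16 CSV dialect with the exact header
  ``seriesuid,coordX,coordY,coordZ,class``.
* Patches are axial (single z slice), windowed to a Hounsfield interval
  and rescaled linearly onto [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .exceptions import FormatError, OutOfBoundsError, EmptyClassError, ParseError

__all__ = [
    "Volume",
    "Candidate",
    "Patch",
    "DEFAULT_HU_WINDOW",
    "read_volume",
    "write_volume",
    "world_to_voxel",
    "voxel_to_world",
    "extract_patch",
    "read_candidates",
    "write_candidates",
    "balance_candidates",
]

#: Standard lung window in HU used to map patches onto [0, 1].
DEFAULT_HU_WINDOW = (-1000.0, 400.0)

CANDIDATE_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "class"]


@dataclass
class Volume:
    """A CT volume: HU voxels (z, y, x) plus world-geometry metadata (x, y, z)."""

    voxels: np.ndarray
    spacing: tuple
    origin: tuple
    direction: tuple = (1, 1, 1)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(int(d) for d in self.direction)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be positive, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError("origin must have 3 entries")
        if any(d not in (-1, 1) for d in self.direction):
            raise ValueError(f"direction entries must be +/-1, got {self.direction}")

    @property
    def shape_zyx(self) -> tuple:
        return self.voxels.shape


@dataclass(frozen=True)
class Candidate:
    """A proposed nodule location in world mm with its binary label."""

    series_id: str
    world_xyz: tuple
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class Patch:
    """An axial candidate-centered patch on the [0, 1] working range."""

    pixels: np.ndarray
    source_series: str
    center_voxel: tuple  # (z, y, x)
    label: int


def read_volume(path) -> Volume:
    """Read an .mhd/.raw MetaImage pair into a :class:`Volume`."""
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume header: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # sitk wraps format problems in RuntimeError
        raise FormatError(f"cannot read {path}: {exc}") from exc
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    off_diag = direction - np.diag(np.diag(direction))
    if np.abs(off_diag).max() > 1e-6:
        raise FormatError(
            f"{path}: TransformMatrix/ElementDirection is not diagonal; "
            "only axis-aligned volumes are supported"
        )
    diag = np.diag(direction)
    if not np.allclose(np.abs(diag), 1.0, atol=1e-6):
        raise FormatError(
            f"{path}: TransformMatrix diagonal must be +/-1, got {tuple(diag)}"
        )
    return Volume(
        voxels=sitk.GetArrayFromImage(img),
        spacing=img.GetSpacing(),
        origin=img.GetOrigin(),
        direction=tuple(int(round(d)) for d in diag),
    )


def write_volume(volume: Volume, path) -> None:
    """Write a :class:`Volume` as an .mhd header plus .raw voxel file.

    Integer voxel data are stored as 16-bit (MET_SHORT), losslessly for
    in-range HU values; floating data keep their floating element type.
    """
    path = str(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    vox = volume.voxels
    if np.issubdtype(vox.dtype, np.integer):
        vox = vox.astype(np.int16)
    img = sitk.GetImageFromArray(vox)
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    d = volume.direction
    img.SetDirection((float(d[0]), 0.0, 0.0,
                      0.0, float(d[1]), 0.0,
                      0.0, 0.0, float(d[2])))
    sitk.WriteImage(img, path, useCompression=False)


def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def world_to_voxel(world_xyz, volume: Volume) -> tuple:
    """World mm -> integer voxel index (z, y, x).

    The continuous index is direction * (world - origin) / spacing per
    axis, rounded half away from zero; it may lie outside the array (the
    caller checks bounds).
    """
    w = np.asarray(world_xyz, dtype=float)
    o = np.asarray(volume.origin)
    s = np.asarray(volume.spacing)
    d = np.asarray(volume.direction)
    cont = d * (w - o) / s  # (x, y, z)
    ix, iy, iz = (int(v) for v in _round_half_away(cont))
    return (iz, iy, ix)


def voxel_to_world(index_zyx, volume: Volume) -> tuple:
    """Integer voxel index (z, y, x) -> world mm (x, y, z); inverse affine."""
    iz, iy, ix = index_zyx
    o = np.asarray(volume.origin)
    s = np.asarray(volume.spacing)
    d = np.asarray(volume.direction)
    world = o + d * np.array([ix, iy, iz], dtype=float) * s
    return tuple(float(v) for v in world)


def extract_patch(
    volume: Volume,
    candidate: Candidate,
    size: int = 51,
    hu_window=DEFAULT_HU_WINDOW,
) -> Patch:
    """Axial size x size patch centered on the candidate.

    HU values are clamped to ``hu_window`` and rescaled linearly to
    [0, 1]; pixels falling outside the volume take the window minimum
    (0.0 after rescaling).
    """
    if size < 3 or size % 2 == 0:
        raise ValueError(f"size must be odd and >= 3, got {size}")
    lo, hi = float(hu_window[0]), float(hu_window[1])
    if not lo < hi:
        raise ValueError(f"hu_window must be ordered, got {hu_window}")
    center = world_to_voxel(candidate.world_xyz, volume)
    cz, cy, cx = center
    nz, ny, nx = volume.shape_zyx
    if not 0 <= cz < nz:
        raise OutOfBoundsError(
            f"candidate z index {cz} outside volume depth {nz}", index=center
        )
    half = size // 2
    out = np.zeros((size, size), dtype=float)
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    sy0, sx0 = max(y0, 0), max(x0, 0)
    sy1, sx1 = min(y1, ny), min(x1, nx)
    if sy0 < sy1 and sx0 < sx1:
        region = volume.voxels[cz, sy0:sy1, sx0:sx1].astype(float)
        scaled = (np.clip(region, lo, hi) - lo) / (hi - lo)
        out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = scaled
    return Patch(
        pixels=out,
        source_series=candidate.series_id,
        center_voxel=center,
        label=candidate.label,
    )


def read_candidates(path) -> list[Candidate]:
    """Parse a LUNA16-style candidates CSV into :class:`Candidate` records."""
    df = pd.read_csv(path, dtype=str)
    for col in CANDIDATE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"candidates file is missing column {col!r}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            coords = tuple(
                float(getattr(row, c)) for c in ("coordX", "coordY", "coordZ")
            )
            label = int(getattr(row, "_4") if hasattr(row, "_4")
                        else getattr(row, "class"))
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"row {i + 2}: cannot parse candidate fields ({exc})"
            ) from exc
        out.append(Candidate(series_id=str(row.seriesuid),
                             world_xyz=coords, label=label))
    return out


def write_candidates(candidates, path) -> None:
    """Write candidates in the exact LUNA16 CSV dialect."""
    pd.DataFrame(
        [
            {
                "seriesuid": c.series_id,
                "coordX": c.world_xyz[0],
                "coordY": c.world_xyz[1],
                "coordZ": c.world_xyz[2],
                "class": c.label,
            }
            for c in candidates
        ],
        columns=CANDIDATE_COLUMNS,
    ).to_csv(path, index=False)


def balance_candidates(candidates, ratio: float = 1.0, seed: int = 0) -> list[Candidate]:
    """Retain every positive; subsample negatives to ``ratio`` positives per
    negative (all negatives if too few); order shuffled deterministically."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    candidates = list(candidates)
    positives = [c for c in candidates if c.label == 1]
    negatives = [c for c in candidates if c.label == 0]
    if not positives:
        raise EmptyClassError("no positive candidates to balance around")
    rng = np.random.default_rng(seed)
    n_neg = min(len(negatives), int(round(len(positives) / ratio)))
    if negatives and n_neg > 0:
        idx = rng.choice(len(negatives), size=n_neg, replace=False)
        chosen = [negatives[i] for i in sorted(idx)]
    else:
        chosen = []
    combined = positives + chosen
    order = rng.permutation(len(combined))
    return [combined[i] for i in order]
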