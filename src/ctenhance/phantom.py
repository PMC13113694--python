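"""Synthetic lung-CT phantoms with known ground truth.

Each phantom is a body ellipsoid of soft tissue (near 0 HU) in air,
containing two lung ellipsoids of parenchyma (near -850 HU).  Spherical
nodules and z-oriented cylindrical vessels of configurable HU are placed
inside the lungs by seeded rejection sampling without mutual overlap, with
edges blended linearly over about one voxel so objects have the weak
partial-volume boundaries enhancement has to work with.  Additive Gaussian
noise emulates acquisition noise, and a per-scan global offset added to
the lung interior emulates the scanner-dependent low / medium / high
intensity regimes seen across real scans.

Everything is deterministic for a fixed config (including the seed), so
generated volumes, truth records and candidate lists double as test
fixtures for the rest of the package.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .ct_io import Candidate, Volume, voxel_to_world, write_candidates, write_volume
from .exceptions import CapacityError

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_volume",
    "generate_candidates",
    "true_lung_mask",
    "write_dataset",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue HU values and corruption settings of one phantom.

    shape is (z, y, x) voxels; spacing and origin are (x, y, z) mm as in
    the MetaImage header.  ``intensity_offset`` shifts every lung-interior
    voxel, emulating a scanner brightness group; ``noise_sd`` is the SD of
    additive Gaussian noise in HU.
    """

    shape: tuple = (64, 128, 128)
    spacing: tuple = (0.7, 0.7, 1.25)
    origin: tuple = (0.0, 0.0, 0.0)
    parenchyma_hu: float = -850.0
    body_hu: float = 0.0
    nodule_count: int = 4
    nodule_radius_range: tuple = (2.0, 5.0)
    nodule_hu_range: tuple = (-50.0, 50.0)
    vessel_count: int = 6
    vessel_radius_range: tuple = (0.8, 1.6)
    vessel_hu: float = 40.0
    noise_sd: float = 20.0
    intensity_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.nodule_radius_range) <= 0 or min(self.vessel_radius_range) <= 0:
            raise ValueError("object radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.nodule_hu_range[0] <= self.parenchyma_hu:
            raise ValueError("nodule HU range must lie above parenchyma_hu")
        if self.nodule_count < 0 or self.vessel_count < 0:
            raise ValueError("object counts must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth of one generated phantom.

    nodules: list of (world center (x, y, z) mm, radius mm, peak HU);
    vessels: list of ((x, y) mm axis position, (z0, z1) mm extent, radius mm);
    the generating config is carried along so downstream sampling (e.g.
    lung-interior negatives) can reuse the analytic geometry.
    """

    nodules: list = field(default_factory=list)
    vessels: list = field(default_factory=list)
    applied_offset: float = 0.0
    config: PhantomConfig | None = None


def _world_axes(config: PhantomConfig):
    """Per-axis world coordinates of voxel centers, plus extents."""
    nz, ny, nx = config.shape
    sx, sy, sz = config.spacing
    ox, oy, oz = config.origin
    xs = ox + np.arange(nx) * sx
    ys = oy + np.arange(ny) * sy
    zs = oz + np.arange(nz) * sz
    return xs, ys, zs


def _lung_geometry(config: PhantomConfig):
    """Centers and semi-axes (mm, world) of the body and both lungs."""
    xs, ys, zs = _world_axes(config)
    cx, cy, cz = xs.mean(), ys.mean(), zs.mean()
    ex = xs[-1] - xs[0]
    ey = ys[-1] - ys[0]
    ez = zs[-1] - zs[0]
    body = ((cx, cy, cz), (0.46 * ex, 0.40 * ey, 0.55 * ez))
    lungs = []
    for side in (-1, 1):
        lungs.append(
            ((cx + side * 0.21 * ex, cy, cz), (0.16 * ex, 0.28 * ey, 0.42 * ez))
        )
    return body, lungs


def _ellipsoid_mask(config: PhantomConfig, center, axes) -> np.ndarray:
    xs, ys, zs = _world_axes(config)
    X = ((xs - center[0]) / axes[0]) ** 2
    Y = ((ys - center[1]) / axes[1]) ** 2
    Z = ((zs - center[2]) / axes[2]) ** 2
    return (Z[:, None, None] + Y[None, :, None] + X[None, None, :]) <= 1.0


def true_lung_mask(config: PhantomConfig) -> np.ndarray:
    """Analytic lung-interior mask (union of both lung ellipsoids)."""
    _, lungs = _lung_geometry(config)
    mask = np.zeros(config.shape, dtype=bool)
    for center, axes in lungs:
        mask |= _ellipsoid_mask(config, center, axes)
    return mask


def _inside_lung(point, lungs, margin: float) -> bool:
    px, py, pz = point
    for (cx, cy, cz), (ax, ay, az) in lungs:
        if (
            ((px - cx) / max(ax - margin, 1e-9)) ** 2
            + ((py - cy) / max(ay - margin, 1e-9)) ** 2
            + ((pz - cz) / max(az - margin, 1e-9)) ** 2
            <= 1.0
        ):
            return True
    return False


def _paint_sphere(vox, config, center, radius, hu):
    """Blend a sphere into the volume with ~1-voxel linear edge falloff."""
    xs, ys, zs = _world_axes(config)
    v = float(np.mean(config.spacing))
    ix = np.flatnonzero(np.abs(xs - center[0]) <= radius + 2 * v)
    iy = np.flatnonzero(np.abs(ys - center[1]) <= radius + 2 * v)
    iz = np.flatnonzero(np.abs(zs - center[2]) <= radius + 2 * v)
    if not (len(ix) and len(iy) and len(iz)):
        return
    dx = xs[ix] - center[0]
    dy = ys[iy] - center[1]
    dz = zs[iz] - center[2]
    dist = np.sqrt(
        dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
    )
    w = np.clip((radius + 0.5 * v - dist) / v, 0.0, 1.0)
    sub = vox[np.ix_(iz, iy, ix)]
    vox[np.ix_(iz, iy, ix)] = (1 - w) * sub + w * hu


def _paint_cylinder(vox, config, axis_xy, z_extent, radius, hu):
    """Blend a z-aligned cylinder (vessel) with 1-voxel edge falloff."""
    xs, ys, zs = _world_axes(config)
    v = float(np.mean(config.spacing))
    ix = np.flatnonzero(np.abs(xs - axis_xy[0]) <= radius + 2 * v)
    iy = np.flatnonzero(np.abs(ys - axis_xy[1]) <= radius + 2 * v)
    iz = np.flatnonzero((zs >= z_extent[0]) & (zs <= z_extent[1]))
    if not (len(ix) and len(iy) and len(iz)):
        return
    dx = xs[ix] - axis_xy[0]
    dy = ys[iy] - axis_xy[1]
    dist = np.sqrt(dy[:, None] ** 2 + dx[None, :] ** 2)
    w2 = np.clip((radius + 0.5 * v - dist) / v, 0.0, 1.0)
    sub = vox[np.ix_(iz, iy, ix)]
    vox[np.ix_(iz, iy, ix)] = (1 - w2[None]) * sub + w2[None] * hu


def generate_volume(config: PhantomConfig):
    """Build one phantom; returns ``(Volume, PhantomTruth)``.

    Deterministic for a fixed config.  Raises
    :class:`~ctenhance.exceptions.CapacityError` when object placement
    keeps colliding (too many or too large objects for the lung size).
    """
    rng = np.random.default_rng(config.seed)
    body, lungs = _lung_geometry(config)
    vox = np.full(config.shape, -1000.0)
    vox[_ellipsoid_mask(config, *body)] = config.body_hu
    lung_mask = true_lung_mask(config)
    vox[lung_mask] = config.parenchyma_hu

    truth = PhantomTruth(applied_offset=config.intensity_offset, config=config)

    placed_nodules = []  # (center, radius)
    for _ in range(config.nodule_count):
        r_lo, r_hi = config.nodule_radius_range
        for _attempt in range(200):
            radius = float(rng.uniform(r_lo, r_hi))
            hu = float(rng.uniform(*config.nodule_hu_range))
            lung = lungs[int(rng.integers(0, len(lungs)))]
            (cx, cy, cz), (ax, ay, az) = lung
            u = rng.uniform(-1, 1, size=3)
            point = (
                cx + u[0] * (ax - radius - 1.0),
                cy + u[1] * (ay - radius - 1.0),
                cz + u[2] * (az - radius - 1.0),
            )
            if not _inside_lung(point, lungs, radius + 1.0):
                continue
            collision = any(
                np.linalg.norm(np.subtract(point, c)) < radius + r + 2.0
                for c, r in placed_nodules
            )
            if collision:
                continue
            placed_nodules.append((point, radius))
            _paint_sphere(vox, config, point, radius, hu)
            truth.nodules.append(
                (tuple(float(p) for p in point), radius,
                 hu + config.intensity_offset)
            )
            break
        else:
            raise CapacityError(
                "could not place all nodules; use fewer or smaller objects"
            )

    xs, ys, zs = _world_axes(config)
    for _ in range(config.vessel_count):
        r_lo, r_hi = config.vessel_radius_range
        for _attempt in range(200):
            radius = float(rng.uniform(r_lo, r_hi))
            lung = lungs[int(rng.integers(0, len(lungs)))]
            (cx, cy, cz), (ax, ay, az) = lung
            u = rng.uniform(-0.7, 0.7, size=2)
            axis_xy = (cx + u[0] * ax, cy + u[1] * ay)
            half_len = 0.5 * az * float(rng.uniform(0.6, 1.0))
            z0, z1 = cz - half_len, cz + half_len
            collision = any(
                np.hypot(axis_xy[0] - c[0], axis_xy[1] - c[1]) < radius + r + 2.0
                and z0 - r <= c[2] <= z1 + r
                for c, r in placed_nodules
            )
            if collision:
                continue
            _paint_cylinder(vox, config, axis_xy, (z0, z1), radius,
                            config.vessel_hu)
            truth.vessels.append(
                ((float(axis_xy[0]), float(axis_xy[1])),
                 (float(z0), float(z1)), radius)
            )
            break
        else:
            raise CapacityError(
                "could not place all vessels; use fewer or smaller objects"
            )

    if config.noise_sd > 0:
        vox += rng.normal(0.0, config.noise_sd, size=config.shape)
    if config.intensity_offset != 0:
        vox[lung_mask] += config.intensity_offset

    volume = Volume(
        voxels=vox,
        spacing=config.spacing,
        origin=config.origin,
        direction=(1, 1, 1),
    )
    return volume, truth


def generate_candidates(
    truth: PhantomTruth,
    volume: Volume,
    n_negatives: int,
    seed: int = 0,
    series_id: str = "phantom-000",
) -> list[Candidate]:
    """Candidate list: one positive per nodule plus sampled negatives.

    Negatives mix hard cases on vessel surfaces with easy cases at random
    lung-interior voxels (at least one vessel-adjacent when vessels
    exist); every returned world coordinate maps back inside the volume.
    """
    if n_negatives < 0:
        raise ValueError("n_negatives must be non-negative")
    if truth.config is None:
        raise ValueError("truth must carry its generating config")
    rng = np.random.default_rng(seed)
    out = [
        Candidate(series_id=series_id, world_xyz=center, label=1)
        for center, _radius, _hu in truth.nodules
    ]
    n_vessel = min(n_negatives // 2, len(truth.vessels) * 2)
    if truth.vessels and n_negatives > 0:
        n_vessel = max(n_vessel, 1)
    for _ in range(n_vessel):
        (axx, axy), (z0, z1), radius = truth.vessels[
            int(rng.integers(0, len(truth.vessels)))
        ]
        theta = float(rng.uniform(0, 2 * np.pi))
        point = (
            axx + radius * np.cos(theta),
            axy + radius * np.sin(theta),
            float(rng.uniform(z0, z1)),
        )
        out.append(Candidate(series_id=series_id,
                             world_xyz=tuple(float(p) for p in point), label=0))
    mask = true_lung_mask(truth.config)
    idx = np.argwhere(mask)
    for _ in range(n_negatives - n_vessel):
        iz, iy, ix = idx[int(rng.integers(0, len(idx)))]
        world = voxel_to_world((int(iz), int(iy), int(ix)), volume)
        out.append(Candidate(series_id=series_id, world_xyz=world, label=0))
    return out


def write_dataset(items, directory, n_negatives: int = 8, seed: int = 0) -> dict:
    """Write phantom volumes, a shared candidates CSV and a truth sidecar.

    ``items`` is a sequence of ``(Volume, PhantomTruth)`` pairs.  Returns a
    manifest dict (also written as ``manifest.json``) listing all paths.
    """
    os.makedirs(directory, exist_ok=True)
    manifest = {"volumes": [], "candidates": None, "truth": None}
    all_candidates = []
    truth_records = []
    for i, (volume, truth) in enumerate(items):
        series_id = f"phantom-{i:03d}"
        mhd_path = os.path.join(directory, f"{series_id}.mhd")
        vol_int = Volume(
            voxels=np.round(volume.voxels).astype(np.int16),
            spacing=volume.spacing,
            origin=volume.origin,
            direction=volume.direction,
        )
        write_volume(vol_int, mhd_path)
        manifest["volumes"].append({"series_id": series_id, "path": mhd_path})
        all_candidates.extend(
            generate_candidates(truth, volume, n_negatives=n_negatives,
                                seed=seed + i, series_id=series_id)
        )
        truth_records.append(
            {
                "series_id": series_id,
                "nodules": truth.nodules,
                "vessels": truth.vessels,
                "applied_offset": truth.applied_offset,
                "config": asdict(truth.config) if truth.config else None,
            }
        )
    csv_path = os.path.join(directory, "candidates.csv")
    write_candidates(all_candidates, csv_path)
    manifest["candidates"] = csv_path
    truth_path = os.path.join(directory, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth_records, fh, indent=2)
    manifest["truth"] = truth_path
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
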