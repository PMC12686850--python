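"""Per-object 3D morphometry: volume, effective diameter, shape metrics.

Size is quantified two ways: the volume (voxel count times per-voxel
volume) and the *effective diameter*, the diameter of the sphere of
equal volume, d = (6V/pi)^(1/3). Shape is quantified two ways:

* **Aspect-length ratios (ALR)** — PCA is run on the physical voxel
  coordinates of an object; the bounding-box extents (lx >= ly >= lz)
  along the three principal axes give the pair (lx/lz, ly/lz), each
  >= 1 and (1, 1) for a perfect sphere.
* **Sphericity** — the surface area of the equal-volume sphere divided
  by the object's surface area, the latter approximated by marching
  cubes on the binary mask; 1.0 iff the object is a perfect sphere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .io import LabelVolume, VoxelSpacing

__all__ = [
    "GlomerulusMorphometry",
    "object_volume",
    "effective_diameter",
    "principal_extents",
    "aspect_length_ratios",
    "surface_area",
    "sphericity",
    "measure_all",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlomerulusMorphometry:
    """One object's complete morphometric record (lengths in um)."""

    label: int
    voxel_count: int
    volume: float
    effective_diameter: float
    lx: float
    ly: float
    lz: float
    alr_xz: float
    alr_yz: float
    surface_area: float
    sphericity: float


def object_volume(voxel_count: int, spacing: VoxelSpacing) -> float:
    """Volume in um^3: voxel count times the effective per-voxel volume."""
    if voxel_count < 1:
        raise ValueError(f"voxel_count must be >= 1, got {voxel_count}")
    return voxel_count * spacing.voxel_volume


def effective_diameter(volume: float) -> float:
    """Diameter of the sphere of equal volume: d = (6V/pi)^(1/3)."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (6.0 * volume / np.pi) ** (1.0 / 3.0)


def principal_extents(
    points: np.ndarray, floor: float | None = None
) -> tuple[float, float, float]:
    """Bounding-box extents along the principal axes of a point cloud.

    The procedure has three steps: center the coordinates on their mean
    (the geometric center), form the covariance matrix, and
    eigendecompose it. Points are projected onto the eigenvectors
    (descending eigenvalue order) and the extent along each axis is
    max - min of the projections. Returned sorted lx >= ly >= lz.

    Parameters
    ----------
    points : (n, 3) array
        Physical coordinates in um (one row per voxel center).
    floor : float, optional
        Lower floor applied to each extent so that degenerate (planar,
        linear, single-point) objects keep a positive smallest extent;
        callers typically pass the smallest spacing dimension.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("empty point set")
    centered = points - points.mean(axis=0)
    if points.shape[0] == 1:
        extents = np.zeros(3)
    else:
        cov = np.cov(centered, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        proj = centered @ eigvecs[:, order]
        extents = proj.max(axis=0) - proj.min(axis=0)
    extents = np.sort(extents)[::-1]
    if floor is not None:
        extents = np.maximum(extents, floor)
    return (float(extents[0]), float(extents[1]), float(extents[2]))


def aspect_length_ratios(extents: tuple[float, float, float]) -> tuple[float, float]:
    """ALR pair (lx/lz, ly/lz) from sorted principal extents."""
    lx, ly, lz = extents
    if lz <= 0:
        raise ValueError(f"smallest extent must be positive, got {lz}")
    return (lx / lz, ly / lz)


def surface_area(
    mask: np.ndarray,
    spacing: VoxelSpacing,
    method: str = "lewiner",
    smoothing_sigma: float = 1.0,
) -> float:
    """Marching-cubes surface area, in um^2, of a binary mask.

    The mask (indexed z, y, x) is padded with background on every face
    so the isosurface at level 0.5 is closed, and vertices are scaled
    by the physical spacing. ``method`` selects the marching cubes
    variant ('lewiner' or 'lorensen').

    By default the 0/1 mask is first smoothed with a Gaussian of
    ``smoothing_sigma`` voxels: meshing the raw binary mask places
    every vertex at an edge midpoint, and the resulting staircase
    overestimates the area of digitized smooth objects by ~9% on an
    isotropic grid and ~16% at a 1.76/5 um anisotropic spacing,
    whereas the smoothed field recovers analytic sphere and spheroid
    areas to within ~2% (checked in the test suite). Pass
    ``smoothing_sigma=0`` for the raw-mask mesh; that variant
    reproduces the depressed sphericity scale that binary meshing
    imposes on anisotropic stacks. Objects too small to carry the
    smoothed isosurface (a few voxels) silently fall back to the
    raw-mask mesh.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a 3D array with at least one foreground voxel")
    if smoothing_sigma > 0:
        pad = max(1, int(np.ceil(3 * smoothing_sigma)))
        field = ndimage.gaussian_filter(
            np.pad(mask, pad).astype(float), sigma=smoothing_sigma
        )
        if field.max() > 0.5:
            verts, faces, _, _ = marching_cubes(
                field, level=0.5, spacing=spacing.zyx, method=method
            )
            return float(mesh_surface_area(verts, faces))
        # object too small for the smoothed isosurface: raw mesh below
    padded = np.pad(mask, 1).astype(np.uint8)
    verts, faces, _, _ = marching_cubes(
        padded, level=0.5, spacing=spacing.zyx, method=method
    )
    return float(mesh_surface_area(verts, faces))


def sphericity(volume: float, area: float) -> float:
    """Surface area of the equal-volume sphere over the object's area.

    Psi = pi^(1/3) (6V)^(2/3) / A; equals 1.0 for a perfect sphere and
    is below 1 for every other continuum shape. Digitization can push
    near-spheres slightly above 1; values > 1 are logged, not clamped.
    """
    if volume <= 0 or area <= 0:
        raise ValueError("volume and surface area must be positive")
    psi = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    if psi > 1.0:
        log.warning("sphericity %.4f exceeds 1 (digitization artifact)", psi)
    return float(psi)


def _object_slices(array: np.ndarray) -> dict[int, tuple[slice, slice, slice]]:
    """Map each positive label to its tight bounding-box slices."""
    max_label = int(array.max())
    slices = ndimage.find_objects(array, max_label=max_label)
    return {lab: sl for lab, sl in zip(range(1, max_label + 1), slices) if sl is not None}


def measure_all(
    vol: LabelVolume,
    marching_cubes_method: str = "lewiner",
    smoothing_sigma: float = 1.0,
) -> pd.DataFrame:
    """Measure every labeled object; one row per label, sorted by id.

    Columns: label, voxel_count, volume_um3, effective_diameter_um,
    lx_um, ly_um, lz_um, alr_xz, alr_yz, surface_area_um2, sphericity.
    An empty volume yields an empty table with a warning.
    """
    spacing = vol.spacing
    floor = min(spacing.dx, spacing.dy, spacing.dz)
    records: list[GlomerulusMorphometry] = []
    boxes = _object_slices(vol.array)
    for label in sorted(boxes):
        sl = boxes[label]
        sub = vol.array[sl] == label
        count = int(sub.sum())
        vol_um3 = object_volume(count, spacing)
        # voxel-center physical coordinates inside the bounding box;
        # PCA is translation-invariant so the box offset is irrelevant
        zz, yy, xx = np.nonzero(sub)
        pts = np.column_stack([
            (xx + 0.5) * spacing.dx,
            (yy + 0.5) * spacing.dy,
            (zz + 0.5) * spacing.dz,
        ])
        extents = principal_extents(pts, floor=floor)
        alr = aspect_length_ratios(extents)
        area = surface_area(sub, spacing, method=marching_cubes_method,
                            smoothing_sigma=smoothing_sigma)
        records.append(GlomerulusMorphometry(
            label=label,
            voxel_count=count,
            volume=vol_um3,
            effective_diameter=effective_diameter(vol_um3),
            lx=extents[0], ly=extents[1], lz=extents[2],
            alr_xz=alr[0], alr_yz=alr[1],
            surface_area=area,
            sphericity=sphericity(vol_um3, area),
        ))
    if not records:
        warnings.warn(f"volume {vol.name!r} contains no labeled objects")
        cols = ["label", "voxel_count", "volume_um3", "effective_diameter_um",
                "lx_um", "ly_um", "lz_um", "alr_xz", "alr_yz",
                "surface_area_um2", "sphericity"]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([asdict(r) for r in records])
    df = df.rename(columns={
        "volume": "volume_um3",
        "effective_diameter": "effective_diameter_um",
        "lx": "lx_um", "ly": "ly_um", "lz": "lz_um",
        "surface_area": "surface_area_um2",
    })
    return df
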