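"""Reading, writing, and validating 3D label volumes.

A label volume is a 3D integer array indexed ``(z, y, x)`` in which the
background is 0 and every positive value identifies one segmented object
(here: one glomerulus). Physical voxel spacing is carried alongside the
array because the stacks this package targets are strongly anisotropic
(e.g. 1.76 x 1.76 um in-plane, 5 um between slices).

Supported on-disk formats are multi-page TIFF (one page per z-slice,
via :mod:`tifffile`) and NRRD with raw encoding (a minimal reader/writer
is included; the format is a text header followed by the raw array).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VoxelSpacing",
    "LabelVolume",
    "read_label_volume",
    "write_label_volume",
    "list_labels",
    "object_coordinates",
    "connected_component_count",
]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel spacing in micrometres.

    Parameters
    ----------
    dx, dy : float
        In-plane pixel size along image x and y, in um.
    dz : float
        Slice step along z, in um.
    voxel_volume_override : float, optional
        If set, this constant (um^3) is used as the per-voxel volume
        instead of ``dx*dy*dz``. Needed to reproduce published numbers
        that quote a rounded per-voxel volume (15.40 um^3 for a
        1.76 x 1.76 x 5 um grid, whose exact product is 15.488 um^3).
    """

    dx: float
    dy: float
    dz: float
    voxel_volume_override: float | None = None

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"spacing must be positive, got {(self.dx, self.dy, self.dz)}")
        if self.voxel_volume_override is not None and self.voxel_volume_override <= 0:
            raise ValueError("voxel_volume_override must be positive")

    @property
    def voxel_volume(self) -> float:
        """Effective per-voxel volume in um^3."""
        if self.voxel_volume_override is not None:
            return self.voxel_volume_override
        return self.dx * self.dy * self.dz

    @property
    def zyx(self) -> tuple[float, float, float]:
        """Spacing ordered like the array axes (z, y, x)."""
        return (self.dz, self.dy, self.dx)


@dataclass
class LabelVolume:
    """A 3D integer label image with physical spacing.

    ``array`` is indexed ``(z, y, x)``; background is 0; label ids need
    not be consecutive.
    """

    array: np.ndarray
    spacing: VoxelSpacing
    name: str = ""

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError(f"label array must be 3D, got shape {self.array.shape}")
        if not np.issubdtype(self.array.dtype, np.integer):
            raise TypeError(f"label array must be integer-typed, got {self.array.dtype}")
        if self.array.shape[0] < 1:
            raise ValueError("label volume needs at least one slice")
        if self.array.min() < 0:
            raise ValueError("label values must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of positive label ids present in the volume."""
        vals = np.unique(self.array)
        return vals[vals > 0]


def read_label_volume(path: str | os.PathLike, spacing: VoxelSpacing, name: str | None = None) -> LabelVolume:
    """Read a multi-page TIFF or NRRD label stack.

    The format is chosen by extension (``.nrrd`` vs anything tifffile
    accepts). ``spacing`` always wins over any file metadata, because
    segmentation products routinely lose or mangle resolution tags.
    """
    path = os.fspath(path)
    if path.lower().endswith(".nrrd"):
        array = _read_nrrd(path)
    else:
        array = tifffile.imread(path)
    array = np.asarray(array)
    if array.ndim == 2:  # single-page stack
        array = array[np.newaxis]
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return LabelVolume(array=array, spacing=spacing, name=name)


def write_label_volume(vol: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label volume as multi-page TIFF or raw-encoded NRRD."""
    path = os.fspath(path)
    if path.lower().endswith(".nrrd"):
        _write_nrrd(path, vol.array, vol.spacing)
    else:
        tifffile.imwrite(path, vol.array, photometric="minisblack")


def list_labels(vol: LabelVolume) -> list[tuple[int, int]]:
    """Return ``(label, voxel_count)`` pairs sorted by label id.

    Background (0) is excluded; counts sum to the number of nonzero
    voxels.
    """
    vals, counts = np.unique(vol.array, return_counts=True)
    keep = vals > 0
    return list(zip(vals[keep].tolist(), counts[keep].tolist()))


def object_coordinates(vol: LabelVolume, label: int) -> np.ndarray:
    """Physical (x, y, z) coordinates, in um, of one object's voxels.

    Each voxel contributes the coordinate of its *center*:
    ``(index + 0.5) * spacing`` per axis. Returns an ``(n, 3)`` array
    ordered (x, y, z).

    Raises
    ------
    KeyError
        If the label is absent from the volume.
    """
    zz, yy, xx = np.nonzero(vol.array == label)
    if zz.size == 0:
        raise KeyError(f"label {label} not present in volume {vol.name!r}")
    s = vol.spacing
    return np.column_stack([
        (xx + 0.5) * s.dx,
        (yy + 0.5) * s.dy,
        (zz + 0.5) * s.dz,
    ])


def connected_component_count(vol: LabelVolume, label: int, connectivity: int = 26) -> int:
    """Number of connected components of one label's voxel set.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full). A
    well-segmented glomerulus should be a single component; this is a
    QC report, not a filter.
    """
    from scipy import ndimage

    mask = vol.array == label
    if not mask.any():
        raise KeyError(f"label {label} not present in volume {vol.name!r}")
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }[connectivity]
    _, n = ndimage.label(mask, structure=structure)
    return int(n)


# --- minimal NRRD (raw encoding) -------------------------------------------

_NRRD_DTYPES = {
    "uint8": np.uint8, "uint16": np.uint16, "uint32": np.uint32,
    "uint64": np.uint64, "int8": np.int8, "int16": np.int16,
    "int32": np.int32, "int64": np.int64,
    "unsigned short": np.uint16, "unsigned int": np.uint32,
    "short": np.int16, "int": np.int32,
}


def _read_nrrd(path: str) -> np.ndarray:
    """Read a raw-encoded attached-data NRRD file (integer types only)."""
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n"):
                break
            if not line:
                raise ValueError(f"{path}: truncated NRRD header")
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":=" in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.strip()
        if fields.get("encoding", "raw") != "raw":
            raise ValueError(f"{path}: only raw encoding is supported")
        dtype_name = fields["type"]
        if dtype_name not in _NRRD_DTYPES:
            raise TypeError(f"{path}: non-integer NRRD type {dtype_name!r}")
        dtype = np.dtype(_NRRD_DTYPES[dtype_name])
        endian = fields.get("endian", "little")
        dtype = dtype.newbyteorder("<" if endian == "little" else ">")
        sizes = tuple(int(s) for s in fields["sizes"].split())
        data = np.frombuffer(fh.read(), dtype=dtype, count=int(np.prod(sizes)))
    # NRRD sizes list the fastest axis first (x, y, z); numpy is C-order.
    return data.reshape(sizes[::-1]).astype(dtype.newbyteorder("="))


def _write_nrrd(path: str, array: np.ndarray, spacing: VoxelSpacing) -> None:
    arr = np.ascontiguousarray(array)
    header = (
        "NRRD0004\n"
        "# label volume written by glomquant\n"
        f"type: {arr.dtype.name}\n"
        "dimension: 3\n"
        f"sizes: {arr.shape[2]} {arr.shape[1]} {arr.shape[0]}\n"
        f"spacings: {spacing.dx} {spacing.dy} {spacing.dz}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(arr.astype(arr.dtype.newbyteorder("<"), copy=False).tobytes())
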