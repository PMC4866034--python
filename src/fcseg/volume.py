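"""Core volume/seed data types and I/O for NIfTI and NRRD scalar volumes.

A scene is a 3-D grid of non-negative integer intensities together with its
voxel spacing.  All public coordinates are 0-based ``(x, y, z)`` voxel
indices; the storage order of the underlying array is an internal detail.
Intensities must already be quantized: float-valued files are rejected
rather than silently rounded, because the affinity lookup table is exact
only for integer intensities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

Coord = tuple[int, int, int]

_NIFTI_EXTS = (".nii", ".nii.gz")
_NRRD_EXTS = (".nrrd",)


@dataclass(frozen=True)
class Volume3D:
    """A 3-D scalar volume of integer intensities.

    Parameters
    ----------
    data:
        Integer array of shape ``(nx, ny, nz)``; values in
        ``[0, intensity_max]``.
    spacing:
        Voxel size ``(sx, sy, sz)`` in millimetres.  Recorded from file
        headers and preserved on write; the affinity model itself is
        isotropic and does not use it.
    intensity_max:
        Largest representable intensity (e.g. 4095 for 12-bit CT).  Sizes
        the affinity lookup table.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_max: int = 4095

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"volume data must be 3-D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(
                f"volume intensities must be integers, got dtype {data.dtype}; "
                "input must be pre-quantized"
            )
        if data.size and int(data.min()) < 0:
            raise ValueError("volume intensities must be non-negative")
        if self.intensity_max < 1:
            raise ValueError("intensity_max must be >= 1")
        if data.size and int(data.max()) > self.intensity_max:
            raise ValueError(
                f"intensity {int(data.max())} exceeds intensity_max={self.intensity_max}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "data", np.ascontiguousarray(data, dtype=np.int32))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def contains(self, c: Sequence[int]) -> bool:
        return all(0 <= int(c[i]) < self.data.shape[i] for i in range(3))


@dataclass(frozen=True)
class SeedSet:
    """Non-empty set of 0-based ``(x, y, z)`` seed voxels, duplicates rejected."""

    coords: tuple[Coord, ...]

    def __post_init__(self) -> None:
        coords = tuple(tuple(int(v) for v in c) for c in self.coords)
        if not coords:
            raise ValueError("seed set must be non-empty")
        for c in coords:
            if len(c) != 3:
                raise ValueError(f"seed {c} is not a 3-D coordinate")
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate seed coordinates")
        object.__setattr__(self, "coords", coords)

    def check_bounds(self, vol: Volume3D) -> None:
        for c in self.coords:
            if not vol.contains(c):
                raise ValueError(f"seed {c} outside volume bounds {vol.shape}")


@dataclass(frozen=True)
class FuzzyScene:
    """Per-voxel connectedness values in ``[0, 1]``: the max-min closure
    of the affinity from the seed set.  Seed voxels carry exactly 1."""

    values: np.ndarray
    seed: SeedSet

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError("fuzzy scene must be 3-D")
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValueError("connectedness values must lie in [0, 1]")
        for c in self.seed.coords:
            if values[c] != 1.0:
                raise ValueError(f"seed {c} must have connectedness exactly 1")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


def _format_of(path: str | os.PathLike) -> str:
    name = str(path).lower()
    if name.endswith(_NIFTI_EXTS):
        return "nifti"
    if name.endswith(_NRRD_EXTS):
        return "nrrd"
    raise ValueError(
        f"unsupported volume format for {path!r}: expected .nii/.nii.gz or .nrrd"
    )


def _read_array(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    fmt = _format_of(path)
    if not Path(path).exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    else:
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); flip to (x, y, z).
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
    return data, spacing  # type: ignore[return-value]


def read_volume(path: str | os.PathLike, intensity_max: int | None = None) -> Volume3D:
    """Read a NIfTI/NRRD volume as an integer :class:`Volume3D`.

    Float-typed files are accepted only when every voxel holds an exact
    integer; otherwise the input is rejected as not pre-quantized.
    ``intensity_max`` defaults to ``max(4095, data.max())``.
    """
    data, spacing = _read_array(path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(np.isfinite(data)) or np.any(data != np.floor(data)):
            raise ValueError(
                f"{path}: non-integer intensities; input must be pre-quantized"
            )
        data = data.astype(np.int64)
    if data.size and int(data.min()) < 0:
        raise ValueError(f"{path}: negative intensities are not supported")
    if intensity_max is None:
        intensity_max = max(4095, int(data.max()) if data.size else 1)
    return Volume3D(data.astype(np.int32), spacing=spacing, intensity_max=intensity_max)


def read_scene(path: str | os.PathLike) -> np.ndarray:
    """Read a previously written fuzzy scene as a float64 array (x, y, z)."""
    data, _ = _read_array(path)
    return np.asarray(data, dtype=np.float64)


def write_volume(obj: Volume3D | FuzzyScene | np.ndarray, path: str | os.PathLike,
                 spacing: tuple[float, float, float] | None = None) -> None:
    """Write a volume (integer dtype preserved) or fuzzy scene (32-bit float)
    to NIfTI or NRRD, keeping header spacing."""
    fmt = _format_of(path)
    if Path(path).is_dir():
        raise IsADirectoryError(f"refusing to write volume to directory {path}")
    if isinstance(obj, Volume3D):
        data, sp = obj.data, obj.spacing
    elif isinstance(obj, FuzzyScene):
        data, sp = obj.values.astype(np.float32), spacing or (1.0, 1.0, 1.0)
    else:
        data = np.asarray(obj)
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        sp = spacing or (1.0, 1.0, 1.0)
    if spacing is not None:
        sp = spacing
    if fmt == "nifti":
        affine = np.diag([sp[0], sp[1], sp[2], 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(sp)
        nib.save(img, str(path))
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in sp))
        sitk.WriteImage(img, str(path))


#: Fixed face-neighbor offset order: (-x, +x, -y, +y, -z, +z).
NEIGHBOR_OFFSETS: tuple[Coord, ...] = (
    (-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1),
)


def neighbors6(c: Sequence[int], vol: Volume3D) -> list[Coord]:
    """In-bounds 6-face neighbors of ``c``, in the fixed order
    (-x, +x, -y, +y, -z, +z) with out-of-bounds entries omitted."""
    c = tuple(int(v) for v in c)
    if not vol.contains(c):
        raise ValueError(f"coordinate {c} outside volume bounds {vol.shape}")
    out: list[Coord] = []
    for dx, dy, dz in NEIGHBOR_OFFSETS:
        d = (c[0] + dx, c[1] + dy, c[2] + dz)
        if vol.contains(d):
            out.append(d)
    return out
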