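"""Volumetric core: voxel grids, intensity/binary volumes, NIfTI I/O.

All downstream stages (canonical maps, lesion loads, synthetic volumes)
operate on volumes that share a single grid. The grid is defined by the
array shape and the NIfTI sform affine; the voxel volume in cc follows
from the determinant of the affine's spatial part. No resampling happens
anywhere in this package: spatial normalisation to a common 2 mm
MNI-like grid is an upstream concern, and cross-volume operations refuse
mismatched grids rather than silently interpolating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, GridMismatchError, VolumeIOError

__all__ = [
    "VoxelGrid",
    "IntensityVolume",
    "BinaryVolume",
    "default_grid",
    "read_volume",
    "write_volume",
    "as_binary",
    "assert_same_grid",
]

#: Tolerance (mm) when comparing affines of two grids.
AFFINE_ATOL_MM = 1e-4


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and affine of a 3-D voxel grid.

    The affine maps 0-based voxel indices to world (MNI-like) mm
    coordinates, as stored in the NIfTI sform. ``voxel_volume_cc`` is
    |det| of the 3x3 spatial part divided by 1000 (mm^3 -> cc); for the
    default isotropic 2 mm grid it is 0.008 cc.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise DimensionalityError(f"grid shape must be a positive triple, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        if not self.voxel_volume_cc > 0:
            raise ValueError("affine spatial part is singular: voxel volume is zero")

    @property
    def voxel_volume_cc(self) -> float:
        return abs(float(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    def matches(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL_MM, rtol=0.0
        )


def default_grid(shape: tuple[int, int, int] = (48, 56, 48), voxel_mm: float = 2.0) -> VoxelGrid:
    """An isotropic MNI-like grid with the origin at the volume centre."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return VoxelGrid(tuple(shape), affine)


@dataclass(frozen=True)
class IntensityVolume:
    """A real-valued scalar field on a voxel grid (FA maps, probability maps...)."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise DimensionalityError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class BinaryVolume:
    """A {0,1} mask on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise DimensionalityError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binary volume must contain only 0 and 1")
        object.__setattr__(self, "values", values.astype(np.uint8))

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def volume_cc(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_cc


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a 3-D NIfTI-1 file into an :class:`IntensityVolume`.

    Raises :class:`VolumeIOError` for unreadable/malformed files and
    :class:`DimensionalityError` for non-3-D images (a trailing
    singleton fourth axis is squeezed, matching common tool output).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except DimensionalityError:
        raise
    except Exception as exc:  # nibabel raises a zoo of types
        raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(data, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path} is {data.ndim}-D; expected a 3-D volume")
    affine = img.affine if img.affine is not None else np.eye(4)
    grid = VoxelGrid(data.shape, affine)
    return IntensityVolume(grid, data)


def write_volume(vol: IntensityVolume | BinaryVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with the grid affine in the sform."""
    path = Path(path)
    if not path.parent.is_dir():
        raise VolumeIOError(f"cannot write {path}: directory {path.parent} does not exist")
    data = np.asarray(vol.values)
    dtype = np.uint8 if isinstance(vol, BinaryVolume) else np.float64
    img = nib.Nifti1Image(data.astype(dtype), np.asarray(vol.grid.affine))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write NIfTI volume {path}: {exc}") from exc


def as_binary(vol: IntensityVolume, threshold: float = 0.5) -> BinaryVolume:
    """Binarise a nearly-binary float volume: values > threshold -> 1.

    Robust to interpolation artifacts in masks that were stored as
    floats somewhere along their history.
    """
    return BinaryVolume(vol.grid, (vol.values > threshold).astype(np.uint8))


def assert_same_grid(a, b) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share a grid.

    Shapes must be equal and affines equal within 0.0001 mm. Overlap
    arithmetic is only defined on a shared grid.
    """
    ga, gb = a.grid, b.grid
    if not ga.matches(gb):
        raise GridMismatchError(
            "volumes are on different grids: "
            f"shapes {ga.shape} vs {gb.shape}, affines\n{ga.affine}\nvs\n{gb.affine}"
        )
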