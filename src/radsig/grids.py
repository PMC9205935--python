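"""Volumetric image and ROI-mask containers with NIfTI round-trip.

The whole pipeline operates on axis-aligned scalar grids with a physical
voxel spacing. World coordinates follow the simple affine
``world = origin + index * spacing`` (0-based indices, no rotation): the
phantom generator emits axis-aligned volumes, so the full NIfTI affine
machinery is not needed, but spacing and origin are preserved through
every operation and on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumetricImage", "RoiMask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Image and mask do not live on the same voxel grid."""


@dataclass
class VolumetricImage:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    values : (nx, ny, nz) float array
        Voxel intensities. Must be finite.
    spacing_mm : 3-tuple of float
        Physical voxel size per axis, in millimetres.
    origin_mm : 3-tuple of float
        World position of voxel (0, 0, 0).
    modality : str
        One of ``"MR"``, ``"CT"`` or ``"LOG"`` (Laplacian-of-Gaussian
        response map).
    meta : dict
        Free-form provenance (scaling divisors, filter widths, ...).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "MR"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("image values must be a non-empty 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray, *, modality: str | None = None,
                    **meta) -> "VolumetricImage":
        """Copy of this image with new voxel data on the same grid."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if modality is not None:
            out.modality = modality
        out.meta = {**self.meta, **meta}
        return out

    def same_grid(self, other: "VolumetricImage | RoiMask") -> bool:
        return (self.shape == other.values.shape
                and np.allclose(self.spacing_mm, other.spacing_mm)
                and np.allclose(self.origin_mm, other.origin_mm))

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.values.astype(np.float32), affine)
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str = "MR") -> "VolumetricImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return cls(data, tuple(float(z) for z in zooms), origin, modality=modality)


@dataclass
class RoiMask:
    """Binary region-of-interest mask aligned to a :class:`VolumetricImage`."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("mask values must be a non-empty 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray) -> "RoiMask":
        return replace(self, values=np.asarray(values).astype(bool))

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.values.astype(np.uint8), affine)
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "RoiMask":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj) > 0.5
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return cls(data, tuple(float(z) for z in zooms), origin)


def check_aligned(image: VolumetricImage, mask: RoiMask) -> None:
    """Raise :class:`GridMismatchError` unless image and mask share a grid."""
    if image.values.shape != mask.values.shape:
        raise GridMismatchError(
            f"image grid {image.values.shape} != mask grid {mask.values.shape}")
    if not np.allclose(image.spacing_mm, mask.spacing_mm):
        raise GridMismatchError(
            f"image spacing {image.spacing_mm} != mask spacing {mask.spacing_mm}")
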