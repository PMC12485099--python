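"""Core image containers: HU-valued CT volumes and aligned binary masks.

Axis convention, fixed for the whole package:

* axis 0 — transversal, right → left
* axis 1 — sagittal, ventral → dorsal
* axis 2 — longitudinal, caudal → cranial

Voxel spacing is stored in millimetres per axis.  Volumes and masks are
plain NumPy arrays wrapped with spacing metadata; NIfTI round-tripping
goes through nibabel with the spacing recorded in the affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

AXIS_TRANSVERSAL = 0
AXIS_SAGITTAL = 1
AXIS_LONGITUDINAL = 2


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield units with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        HU values; must be finite.
    spacing_mm : tuple of float
        Voxel edge length along each axis in mm; strictly positive.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"CT volume must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CT volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        return nib.Nifti1Image(self.data.astype(np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "CTVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj, dtype=np.float64), spacing)


@dataclass
class BinaryMask:
    """A boolean grid aligned voxel-for-voxel with a :class:`CTVolume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def intersect(self, other: "BinaryMask", name: str = "") -> "BinaryMask":
        check_aligned(self, other)
        return BinaryMask(self.data & other.data, self.spacing_mm, name=name)

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        return nib.Nifti1Image(self.data.astype(np.uint8), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, name: str = "") -> "BinaryMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj) > 0, spacing, name=name)


def check_aligned(a, b) -> None:
    """Raise if two volumes/masks do not share grid shape and spacing."""
    if a.shape != b.shape:
        raise ValueError(f"misaligned grids: shapes {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm):
        raise ValueError(f"misaligned grids: spacings {a.spacing_mm} vs {b.spacing_mm}")
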