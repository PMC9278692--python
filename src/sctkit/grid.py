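"""Common 3D grid containers shared by every stage of the pipeline.

All volumes follow one coordinate convention: voxel indices are 0-based in
axis order (z, y, x); the world position of a voxel center is
``origin + index * spacing`` in millimetres.  Keeping a single convention
across simulation, metrics and dosimetry removes the registration ambiguity
that clinical systems resolve with DICOM frame-of-reference bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = ["ImageVolume", "StructureMask", "StructureSet", "DoseGrid"]


def _as_triple(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float).ravel()
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3:
        raise ValueError(f"expected a scalar or length-3 sequence, got {v!r}")
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class ImageVolume:
    """A 3D scalar grid (HU, relative electron density, ...) with geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values.
    spacing : sequence of 3 floats
        Voxel size in mm per axis, (z, y, x) order.
    origin : sequence of 3 floats
        World position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume | StructureMask | DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other, what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"{what} must share one grid: {self.shape}/{self.spacing} vs "
                f"{other.shape}/{other.spacing}"
            )

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Voxel indices (n, 3) -> world mm coordinates (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data))

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy())


@dataclass
class StructureMask:
    """A named binary mask on an :class:`ImageVolume` grid."""

    name: str
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def centroid_mm(self) -> np.ndarray:
        """World-coordinate centroid of the mask (mm)."""
        if self.is_empty():
            raise ValueError(f"mask {self.name!r} is empty")
        idx = np.argwhere(self.data).astype(float)
        return np.asarray(self.origin) + idx.mean(axis=0) * np.asarray(self.spacing)

    def same_grid(self, other) -> bool:
        return ImageVolume.same_grid(self, other)  # type: ignore[arg-type]

    def with_data(self, data: np.ndarray) -> "StructureMask":
        return replace(self, data=np.asarray(data).astype(bool))


class StructureSet:
    """An ordered mapping of organ name -> :class:`StructureMask` on one grid."""

    def __init__(self, masks: Mapping[str, StructureMask] | None = None):
        self._masks: dict[str, StructureMask] = {}
        if masks:
            for name, m in masks.items():
                self.add(m if m.name == name else replace(m, name=name))

    def add(self, mask: StructureMask) -> None:
        if self._masks:
            first = next(iter(self._masks.values()))
            if not first.same_grid(mask):
                raise ValueError("all masks in a StructureSet must share one grid")
        self._masks[mask.name] = mask

    def __getitem__(self, name: str) -> StructureMask:
        return self._masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def __len__(self) -> int:
        return len(self._masks)

    def names(self) -> list[str]:
        return list(self._masks)

    def items(self):
        return self._masks.items()

    def values(self):
        return self._masks.values()

    def copy(self) -> "StructureSet":
        return StructureSet({n: replace(m, data=m.data.copy()) for n, m in self.items()})


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on an image grid, with the plan's prescription.

    ``valid`` marks voxels carrying a trustworthy value; resampling marks
    voxels that fell outside the source extent as invalid and downstream
    gamma statistics exclude them.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    prescription_gy: float = 50.0
    fractions: int = 5
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"dose grid must be 3D, got shape {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("dose must be non-negative everywhere")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid).astype(bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("valid mask must match dose shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other) -> bool:
        return ImageVolume.same_grid(self, other)  # type: ignore[arg-type]

    def require_same_grid(self, other, what: str = "dose grids") -> None:
        ImageVolume.require_same_grid(self, other, what)  # type: ignore[arg-type]

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        return ImageVolume.world_coords(self, indices)  # type: ignore[arg-type]

    def with_data(self, data: np.ndarray, valid: np.ndarray | None = None) -> "DoseGrid":
        return replace(self, data=np.asarray(data, dtype=float),
                       valid=self.valid.copy() if valid is None else valid)
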