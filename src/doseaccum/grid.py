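"""Axis-aligned 3D grids and the scalar/vector volumes defined on them.

All volumes in this package live on an axis-aligned grid with 0-based
indices, world coordinate = origin + index * spacing, in millimetres.
Array axis order is (x, y, z): x = patient left-right, y =
anterior-posterior, z = superior-inferior (longitudinal).  No oblique
orientations are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Grid", "ImageVolume", "DoseGrid", "mask_volume_cc"]


@dataclass(frozen=True)
class Grid:
    """Geometry of an axis-aligned voxel grid (mm units)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid is strictly three-dimensional")
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"non-positive grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays, broadcastable to ``shape``."""
        ax = []
        for i in range(3):
            c = self.origin[i] + np.arange(self.shape[i]) * self.spacing[i]
            shp = [1, 1, 1]
            shp[i] = self.shape[i]
            ax.append(c.reshape(shp))
        return tuple(ax)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) index coordinates for world points (N, 3)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        i = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + i * np.asarray(self.spacing)

    def same_geometry(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def require_same_geometry(self, other: "Grid", what: str = "volumes") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"grid geometry mismatch between {what}: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )


@dataclass
class ImageVolume:
    """A 3D scalar image in Hounsfield units on a :class:`Grid`.

    ``role`` tags provenance: "pCT", "CBCT", "mCBCT", ...
    """

    grid: Grid
    values: np.ndarray
    role: str = "image"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def copy(self, **changes) -> "ImageVolume":
        out = replace(self, values=self.values.copy(), metadata=dict(self.metadata))
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass
class DoseGrid:
    """A 3D absorbed-dose distribution in Gy on a :class:`Grid`.

    ``role`` is one of pD / ecD_i / mdD_i / sum_ecD / sum_mdD.
    """

    grid: Grid
    values: np.ndarray
    role: str = "dose"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.values < -1e-9):
            raise ValueError("dose values must be non-negative")
        np.clip(self.values, 0.0, None, out=self.values)

    def copy(self, **changes) -> "DoseGrid":
        out = replace(self, values=self.values.copy())
        for k, v in changes.items():
            setattr(out, k, v)
        return out


def mask_volume_cc(mask: np.ndarray, grid: Grid) -> float:
    """Volume of a binary mask by voxel counting."""
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    return float(np.count_nonzero(mask)) * grid.voxel_volume_cc
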