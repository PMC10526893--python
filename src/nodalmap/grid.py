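"""Voxel-grid geometry shared by every volume in the package.

An :class:`ImageGrid` fixes the coordinate contract: *world* coordinates are
millimetres in the scanner/header frame, *voxel* coordinates are fractional
array indices, and ``origin`` is the world coordinate of the **center** of
voxel (0, 0, 0).  The internal canonical orientation is RAS+ (+x right,
+y anterior, +z superior); files are reoriented on load so that bilateral
left/right levels can never be silently flipped.

Label maps are piecewise constant, so point lookups use the *nearest voxel
center*, with indices rounded half away from zero on each axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ORTHO_TOL = 1e-6


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, halves away from zero (per element)."""
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3D volume: shape, spacing (mm), origin (mm), axis directions.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    spacing
        Voxel size in mm along each axis; strictly positive.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    direction
        3x3 orthonormal matrix whose columns are the world directions of the
        voxel axes.  Defaults to identity (axis-aligned RAS+).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        D = np.asarray(self.direction, dtype=float)
        if D.shape != (3, 3):
            raise ValueError(f"direction must be 3x3, got {D.shape}")
        object.__setattr__(self, "direction", tuple(tuple(row) for row in D))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(D.T @ D, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix is not orthonormal within 1e-6")

    # -- derived geometry ---------------------------------------------------

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        A = np.eye(4)
        A[:3, :3] = self.direction_matrix * np.asarray(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size spanned by voxel centers along each axis (mm)."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    # -- coordinate transforms ---------------------------------------------

    def voxel_to_world(self, idx) -> np.ndarray:
        """Map (fractional) voxel indices, shape (..., 3), to world mm."""
        idx = np.asarray(idx, dtype=float)
        D = self.direction_matrix
        return (idx * np.asarray(self.spacing)) @ D.T + np.asarray(self.origin)

    def world_to_voxel(self, pts) -> np.ndarray:
        """Map world-mm points, shape (..., 3), to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        D = self.direction_matrix
        return ((pts - np.asarray(self.origin)) @ D) / np.asarray(self.spacing)

    def nearest_voxel(self, pts) -> np.ndarray:
        """Nearest voxel index (round half away from zero), shape (..., 3)."""
        return round_half_away(self.world_to_voxel(pts))

    def contains_index(self, idx) -> np.ndarray:
        """Boolean mask: integer indices within array bounds."""
        idx = np.asarray(idx)
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)

    def contains_point(self, pts) -> np.ndarray:
        """Boolean mask: world points within the physical voxel-center extent."""
        v = self.world_to_voxel(pts)
        return np.all((v >= -0.5) & (v <= np.asarray(self.shape) - 0.5), axis=-1)

    def all_voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    # -- comparison ---------------------------------------------------------

    def same_geometry(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        """True when two grids agree in shape and (within *tol*) in geometry."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction_matrix, other.direction_matrix, atol=tol)
        )

    def describe(self) -> str:
        return (
            f"ImageGrid(shape={self.shape}, spacing={self.spacing}, "
            f"origin={tuple(round(o, 6) for o in self.origin)})"
        )


def grid_from_affine(affine: np.ndarray, shape) -> ImageGrid:
    """Recover an :class:`ImageGrid` from a 4x4 NIfTI affine and array shape."""
    A = np.asarray(affine, dtype=float)
    M = A[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("affine has a zero-length voxel axis")
    direction = M / spacing
    return ImageGrid(
        shape=tuple(int(n) for n in shape[:3]),
        spacing=tuple(spacing),
        origin=tuple(A[:3, 3]),
        direction=tuple(tuple(row) for row in direction),
    )


def isotropic_like(grid: ImageGrid, spacing_mm: float) -> ImageGrid:
    """An axis-aligned grid covering the same physical extent at isotropic spacing.

    Used as the default kernel-density evaluation grid: the template's
    anisotropic CT grid (e.g. 3 mm slices) is replaced by an isotropic grid
    with the same origin and orientation.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    extent = grid.extent_mm
    shape = tuple(int(np.floor(e / spacing_mm)) + 1 for e in extent)
    return ImageGrid(
        shape=shape,
        spacing=(spacing_mm,) * 3,
        origin=grid.origin,
        direction=grid.direction,
    )
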