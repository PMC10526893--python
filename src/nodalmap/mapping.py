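"""Mapping node centers from patient space into a common template anatomy.

A patient→template :class:`SpatialTransform` is an affine (3x3 matrix +
translation, mm) optionally composed with a dense displacement field
defined on a template-space grid: ``y = A x + b`` followed by
``y' = y + v(y)`` with v sampled by trilinear interpolation (values in mm).
Outside the displacement grid the nearest-edge value is used, with a
warning.

Computing the transforms themselves (intensity-based registration) is
delegated to a pluggable backend.  Built-in backends: ``identity`` and the
``synthetic`` test double that replays a phantom cohort's stored ground-
truth transforms.  Production transforms (e.g. a rigid → affine →
B-spline-SyN chain with cross-correlation and cost-function masking over
tumor/nodal GTV voxels) are computed externally and loaded from a
documented file pair: a 4x4 text affine plus a NIfTI vector field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, MappingError, TransformError
from .grid import ImageGrid, grid_from_affine
from .volume_io import MAPPED_COLUMNS, BinaryMask

logger = logging.getLogger(__name__)

EXTERNAL_RECIPE = """\
External registration recipe (computed outside this package):
  1. rigid, then affine, then B-spline-SyN deformable registration of the
     patient CT (moving) to the template CT (fixed), cross-correlation
     similarity metric;
  2. cost-function masking: voxels of the primary tumor and nodal GTVs are
     excluded from the similarity computation so pathology does not distort
     the alignment;
  3. export the patient->template transform as a 4x4 text affine matrix
     (world mm) plus a dense displacement field (NIfTI, 4th dimension = 3,
     values in mm, defined on the template grid).
Load the exported pair with SpatialTransform.from_files(...).
"""


@dataclass(frozen=True)
class DisplacementField:
    """Dense mm displacement vectors over a template-space grid."""

    grid: ImageGrid
    values: np.ndarray  # shape grid.shape + (3,)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if not np.issubdtype(values.dtype, np.floating):
            values = values.astype(np.float64)
        if values.shape != self.grid.shape + (3,):
            raise TransformError(
                f"displacement shape {values.shape} != grid shape {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(values)):
            raise TransformError("displacement field contains non-finite values")
        object.__setattr__(self, "values", values)

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear displacement at world points (N, 3); edge-clamped outside."""
        vox = self.grid.world_to_voxel(pts)
        if np.any(~self.grid.contains_point(pts)):
            warnings.warn(
                "points outside the displacement grid: using nearest-edge values",
                stacklevel=2,
            )
        coords = vox.T
        return np.stack(
            [
                ndimage.map_coordinates(
                    self.values[..., c], coords, order=1, mode="nearest"
                )
                for c in range(3)
            ],
            axis=-1,
        )


@dataclass(frozen=True)
class SpatialTransform:
    """Patient→template map: affine then (optional) displacement."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    displacement: DisplacementField | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if M.shape != (3, 3) or t.shape != (3,):
            raise TransformError("affine must be a 3x3 matrix and length-3 translation")
        if abs(np.linalg.det(M)) <= 1e-9:
            raise TransformError("affine matrix is numerically singular")
        object.__setattr__(self, "matrix", M)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls()

    def apply(self, pts) -> np.ndarray:
        """Map world points, shape (..., 3) or (3,), patient → template."""
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        pts2 = pts.reshape(-1, 3)
        if not np.all(np.isfinite(pts2)):
            raise TransformError("cannot map non-finite coordinates")
        y = pts2 @ self.matrix.T + self.translation
        if self.displacement is not None:
            y = y + self.displacement.sample(y)
        return y[0] if single else y.reshape(pts.shape)

    # -- file interchange ---------------------------------------------------

    def to_files(self, affine_path, displacement_path=None) -> None:
        """Write the 4x4 text affine (and optional NIfTI displacement field)."""
        A = np.eye(4)
        A[:3, :3] = self.matrix
        A[:3, 3] = self.translation
        np.savetxt(affine_path, A, fmt="%.17g")
        if self.displacement is not None:
            if displacement_path is None:
                raise TransformError("transform has a displacement field but no path given")
            img = nib.Nifti1Image(
                self.displacement.values.astype(np.float32),
                self.displacement.grid.affine,
            )
            nib.save(img, str(displacement_path))

    @classmethod
    def from_files(cls, affine_path, displacement_path=None) -> "SpatialTransform":
        A = np.loadtxt(affine_path)
        if A.shape != (4, 4):
            raise TransformError(f"{affine_path}: expected a 4x4 matrix, got {A.shape}")
        displacement = None
        if displacement_path is not None:
            img = nib.load(str(displacement_path))
            data = np.asanyarray(img.dataobj).astype(float)
            if data.ndim != 4 or data.shape[3] != 3:
                raise TransformError(
                    f"{displacement_path}: displacement must be 4D with 3 components"
                )
            grid = grid_from_affine(img.affine, data.shape[:3])
            displacement = DisplacementField(grid=grid, values=data)
        return cls(matrix=A[:3, :3], translation=A[:3, 3], displacement=displacement)


def map_cohort(
    nodes: pd.DataFrame,
    transforms: dict[str, SpatialTransform],
    template_body: BinaryMask | None = None,
) -> pd.DataFrame:
    """Map a cohort node table into template space (``mapped.csv`` schema).

    Every node's patient-space center is pushed through its patient's
    transform.  ``in_body`` flags whether the mapped center lands in the
    template body mask (always True when no mask is given); out-of-body
    nodes are logged.
    """
    if len(nodes) == 0:
        return pd.DataFrame(columns=MAPPED_COLUMNS)
    missing = sorted(set(nodes["patient_id"]) - set(transforms))
    if missing:
        raise MappingError(f"no transform for patients {missing}")
    rows = []
    for rec in nodes.itertuples(index=False):
        mapped = transforms[rec.patient_id].apply(
            np.array([rec.x_mm, rec.y_mm, rec.z_mm])
        )
        in_body = True
        if template_body is not None:
            vox = template_body.grid.nearest_voxel(mapped)
            in_body = bool(template_body.grid.contains_index(vox)) and bool(
                template_body.values[tuple(vox)]
            )
        if not in_body:
            logger.warning(
                "node %s/%s maps outside the template body", rec.patient_id, rec.node_id
            )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "node_id": rec.node_id,
                "x_mm": mapped[0],
                "y_mm": mapped[1],
                "z_mm": mapped[2],
                "in_body": in_body,
            }
        )
    return pd.DataFrame(rows, columns=MAPPED_COLUMNS)


# ---------------------------------------------------------------------------
# registration backend registry
# ---------------------------------------------------------------------------

def _identity_backend(moving=None, fixed=None, exclusion_mask=None) -> SpatialTransform:
    """Backend returning the identity transform (volumes already co-registered)."""
    return SpatialTransform.identity()


class SyntheticBackend:
    """Test double replaying a phantom cohort's stored ground-truth transforms.

    Construct with a mapping ``patient_id -> SpatialTransform`` (e.g. from
    :meth:`nodalmap.phantom.CohortBundle.transforms`); calling it with a
    patient id returns the stored transform.
    """

    def __init__(self, transforms: dict[str, SpatialTransform]):
        self._transforms = dict(transforms)

    def __call__(self, patient_id, fixed=None, exclusion_mask=None) -> SpatialTransform:
        try:
            return self._transforms[patient_id]
        except KeyError:
            raise MappingError(f"synthetic backend has no transform for {patient_id!r}")


def get_backend(name: str, **kwargs):
    """Resolve a registration backend by configured name.

    ``identity`` and ``synthetic`` are built in; ``external:<name>`` raises
    a configuration error carrying the documented external recipe, since
    intensity-based registration is not computed by this package.
    """
    if name == "identity":
        return _identity_backend
    if name == "synthetic":
        transforms = kwargs.get("transforms")
        if transforms is None:
            raise ConfigurationError("synthetic backend requires transforms=...")
        return SyntheticBackend(transforms)
    if name.startswith("external:"):
        raise ConfigurationError(
            f"backend {name!r} is not executed by this package.\n{EXTERNAL_RECIPE}"
        )
    raise ConfigurationError(
        f"unknown registration backend {name!r} "
        "(expected 'identity', 'synthetic' or 'external:<name>')"
    )
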