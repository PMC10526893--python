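"""Volume and table I/O with a single enforced coordinate convention.

All volumes are NIfTI-1.  On load every volume is reoriented to the
canonical RAS+ orientation (via nibabel), so that left/right — which matters
for the bilateral nodal levels — is unambiguous package-wide.  Grid
mismatches between companion volumes are hard errors; nothing is resampled
silently because assignment distances are measured in mm on these grids.

Tables are CSV (RFC 4180, UTF-8, one header row).  Column schemas
(schema version 1):

``nodes.csv``
    patient_id, node_id, x_mm, y_mm, z_mm, voxel_count, component_id
``assignments.csv``
    patient_id, node_id, level, inside, distance_mm, runner_up, runner_up_margin_mm
``votes.csv``
    patient_id, node_id, reader_id, verdict, corrected_level
    (verdict is ``confirm`` or ``correct``; corrected_level empty for confirms)
``mapped.csv``
    patient_id, node_id, x_mm, y_mm, z_mm, in_body
``distribution.csv``
    level, count, proportion
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GridMismatchError, VolumeFormatError
from .grid import ImageGrid, grid_from_affine
from .levels import CODE_TO_NAME

TABLE_SCHEMA_VERSION = 1

NODES_COLUMNS = ["patient_id", "node_id", "x_mm", "y_mm", "z_mm", "voxel_count", "component_id"]
ASSIGNMENTS_COLUMNS = [
    "patient_id", "node_id", "level", "inside", "distance_mm", "runner_up", "runner_up_margin_mm",
]
VOTES_COLUMNS = ["patient_id", "node_id", "reader_id", "verdict", "corrected_level"]
MAPPED_COLUMNS = ["patient_id", "node_id", "x_mm", "y_mm", "z_mm", "in_body"]
DISTRIBUTION_COLUMNS = ["level", "count", "proportion"]


# ---------------------------------------------------------------------------
# in-memory volume types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelLabelVolume:
    """Integer label map over a grid: 0 = background, 1..20 = level codes."""

    grid: ImageGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise VolumeFormatError(f"labels must be integer, got dtype {labels.dtype}")
        if labels.shape != self.grid.shape:
            raise GridMismatchError(
                f"label array shape {labels.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "labels", labels)

    def present_codes(self) -> list[int]:
        """Sorted nonzero label codes present in the volume."""
        return sorted(int(c) for c in np.unique(self.labels) if c != 0)

    def mask_for(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} mask over a grid (e.g. a lymph-node GTV segmentation)."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask array shape {values.shape} != grid shape {self.grid.shape}"
            )
        bad = np.setdiff1d(np.unique(values), [0, 1])
        if bad.size:
            raise VolumeFormatError(f"mask contains non-binary values {bad.tolist()}")
        object.__setattr__(self, "values", values.astype(np.uint8))

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


def require_same_grid(a, b, what: str = "volumes") -> None:
    """Raise :class:`GridMismatchError` naming both grids unless they agree."""
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError(
            f"{what} are on different grids: {a.grid.describe()} vs {b.grid.describe()}"
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_canonical(path) -> tuple[np.ndarray, ImageGrid]:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {img.shape}")
    img = nib.as_closest_canonical(img)  # reorient to RAS+
    data = np.asanyarray(img.dataobj)
    grid = grid_from_affine(img.affine, img.shape)
    return data, grid


def _as_integer(data: np.ndarray, path) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.int32)
    rounded = np.rint(data)
    if not np.array_equal(rounded, data):
        raise VolumeFormatError(f"{path}: volume is not integer-valued")
    return rounded.astype(np.int32)


def read_label_volume(path) -> LevelLabelVolume:
    """Read a nodal-level label volume; warns about codes outside 1..20."""
    data, grid = _load_canonical(path)
    labels = _as_integer(data, path)
    unknown = sorted(
        int(c) for c in np.unique(labels) if c != 0 and int(c) not in CODE_TO_NAME
    )
    if unknown:
        warnings.warn(
            f"{path}: unmapped label values {unknown} (vocabulary is 1..20)",
            stacklevel=2,
        )
    return LevelLabelVolume(grid=grid, labels=labels)


def read_binary_mask(path) -> BinaryMask:
    """Read a {0,1} mask volume; any other value is rejected."""
    data, grid = _load_canonical(path)
    values = _as_integer(data, path)
    return BinaryMask(grid=grid, values=values)


def write_label_volume(volume: LevelLabelVolume, path) -> None:
    img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.grid.affine)
    nib.save(img, str(path))


def write_binary_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def write_scalar_volume(values: np.ndarray, grid: ImageGrid, path) -> None:
    """Write a float scalar field (e.g. a density map) on a grid."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_scalar_volume(path) -> tuple[np.ndarray, ImageGrid]:
    data, grid = _load_canonical(path)
    return np.asarray(data, dtype=np.float64), grid


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_STRING_COLUMNS = {
    "patient_id": str,
    "reader_id": str,
    "level": str,
    "runner_up": str,
    "verdict": str,
    "corrected_level": str,
}


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    dtypes = {c: _STRING_COLUMNS[c] for c in columns if c in _STRING_COLUMNS}
    df = pd.read_csv(path, dtype=dtypes, keep_default_na=False, na_values=[""])
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise VolumeFormatError(f"{path}: missing columns {missing}")
    return df[columns]


def _write_csv(df: pd.DataFrame, path, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise VolumeFormatError(f"cannot write {path}: missing columns {missing}")
    df[columns].to_csv(path, index=False, lineterminator="\n")


def read_nodes_csv(path) -> pd.DataFrame:
    return _read_csv(path, NODES_COLUMNS)


def write_nodes_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df, path, NODES_COLUMNS)


def read_assignments_csv(path) -> pd.DataFrame:
    return _read_csv(path, ASSIGNMENTS_COLUMNS)


def write_assignments_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df, path, ASSIGNMENTS_COLUMNS)


def read_votes_csv(path) -> pd.DataFrame:
    return _read_csv(path, VOTES_COLUMNS)


def write_votes_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df, path, VOTES_COLUMNS)


def read_mapped_csv(path) -> pd.DataFrame:
    return _read_csv(path, MAPPED_COLUMNS)


def write_mapped_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df, path, MAPPED_COLUMNS)


def read_distribution_csv(path) -> pd.DataFrame:
    return _read_csv(path, DISTRIBUTION_COLUMNS)


def write_distribution_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df, path, DISTRIBUTION_COLUMNS)


# ---------------------------------------------------------------------------
# DICOM-RT STRUCT adapter (optional)
# ---------------------------------------------------------------------------

def rasterize_planar_contours(
    contours: list[np.ndarray], grid: ImageGrid
) -> BinaryMask:
    """Rasterize axial planar contours (world mm) to a mask on *grid*.

    Each contour is an (N, 3) polygon with constant z.  The rasterization
    rule is *voxel-center-in-polygon*: a voxel is foreground when its center
    lies inside (or on the boundary of) the polygon on the nearest slice.
    Multiple contours on one slice are OR-ed together (no hole support).

    This is the documented rule of the DICOM-RT adapter; treatment planning
    systems do not export one, so the convention is this package's choice.
    """
    from matplotlib.path import Path as MplPath

    values = np.zeros(grid.shape, dtype=np.uint8)
    if not np.allclose(grid.direction_matrix, np.eye(3)):
        raise VolumeFormatError("contour rasterization requires an axis-aligned grid")
    nx, ny, _ = grid.shape
    # in-plane voxel-center coordinates
    xs = grid.origin[0] + np.arange(nx) * grid.spacing[0]
    ys = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    for contour in contours:
        contour = np.asarray(contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 3:
            raise VolumeFormatError("contours must be (N, 3) world-mm polygons")
        if np.ptp(contour[:, 2]) > 1e-6:
            raise VolumeFormatError("contour is not planar in z")
        k = int(round((contour[0, 2] - grid.origin[2]) / grid.spacing[2]))
        if not 0 <= k < grid.shape[2]:
            continue
        path = MplPath(contour[:, :2])
        inside = path.contains_points(pts, radius=1e-9).reshape(nx, ny)
        values[:, :, k] |= inside.astype(np.uint8)
    return BinaryMask(grid=grid, values=values)


def rasterize_rtstruct(path, roi_name: str, grid: ImageGrid) -> BinaryMask:
    """Rasterize one ROI of a DICOM-RT STRUCT file onto *grid*.

    Requires ``pydicom`` (optional dependency).  Contour data are read as
    world-mm triplet lists and passed to :func:`rasterize_planar_contours`.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    roi_numbers = {
        roi.ROIName: roi.ROINumber for roi in ds.StructureSetROISequence
    }
    if roi_name not in roi_numbers:
        raise VolumeFormatError(
            f"{path}: ROI {roi_name!r} not found (available: {sorted(roi_numbers)})"
        )
    number = roi_numbers[roi_name]
    contours = []
    for roi_contour in ds.ROIContourSequence:
        if roi_contour.ReferencedROINumber != number:
            continue
        for c in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(data)
    return rasterize_planar_contours(contours, grid)
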