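"""Cohort 3D probability distribution of mapped node centers.

The spatial distribution of lymph node metastases over the template
anatomy is estimated by kernel density estimation: one equal-weight
Gaussian kernel per mapped node center, bandwidth in template-space mm
(default 4 mm), distances measured with a p-norm (default p = 2, the
standard isotropic Gaussian).  The density is evaluated exactly at the
voxel centers of an evaluation grid (each kernel on a truncated local
window) and then discretely renormalized so the voxel sum times the voxel
volume is 1.

Per-level involvement is predicted by partitioning every template voxel
into exactly one level with the *same* rule used for nodes (inside a
level, else nearest level, canonical tie-break) and summing the density
mass over each level's cell.  Because the partition is exhaustive the
residual mass outside all cells is identically zero and renormalization
over levels is a no-op.  The predicted distribution is compared with an
observed cohort distribution by a Pearson chi-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DensityError
from .grid import ImageGrid, round_half_away
from .levels import LEVEL_NAMES, name_for
from .volume_io import LevelLabelVolume, read_scalar_volume, write_scalar_volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DensityParams:
    """Kernel density estimation parameters.

    bandwidth_mm
        Gaussian kernel standard deviation in template-space mm (default 4).
    norm
        p-norm exponent used in the kernel argument (default 2; p = 2 is
        the separable isotropic Gaussian).
    grid_spacing_mm
        Isotropic spacing of the default evaluation grid.
    truncate
        Kernel support radius in bandwidth multiples; beyond this the
        kernel is treated as zero.  At the default 6 the truncated mass is
        ~1e-9 of a kernel.
    """

    bandwidth_mm: float = 4.0
    norm: float = 2.0
    grid_spacing_mm: float = 2.0
    truncate: float = 6.0

    def __post_init__(self) -> None:
        if self.bandwidth_mm <= 0:
            raise DensityError("bandwidth_mm must be > 0")
        if self.norm < 1:
            raise DensityError("norm must be >= 1")
        if self.grid_spacing_mm <= 0:
            raise DensityError("grid_spacing_mm must be > 0")


@dataclass(frozen=True)
class DensityMap:
    """Nonnegative scalar field over a template-space grid, integrating to 1."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise DensityError(
                f"density shape {values.shape} != grid shape {self.grid.shape}"
            )
        if np.any(values < 0):
            raise DensityError("density values must be nonnegative")
        object.__setattr__(self, "values", values)

    @property
    def integral(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume)


def estimate_density(
    points, grid: ImageGrid, params: DensityParams | None = None
) -> DensityMap:
    """Gaussian KDE of mapped node centers, evaluated on *grid*.

    Points are world-mm coordinates, shape (N, 3).  The grid must be
    axis-aligned (template grids are); each kernel is evaluated exactly at
    voxel centers within ``truncate x bandwidth`` of its point, with a
    separable fast path for the Euclidean norm.
    """
    params = params or DensityParams()
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise DensityError("density estimation requires at least one point")
    if not np.all(np.isfinite(pts)):
        raise DensityError("points contain non-finite coordinates")
    if not np.allclose(grid.direction_matrix, np.eye(3)):
        raise DensityError("density evaluation requires an axis-aligned grid")

    sigma = params.bandwidth_mm
    radius = params.truncate * sigma
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)
    values = np.zeros(grid.shape, dtype=float)

    n_clipped = 0
    for p in pts:
        lo = np.maximum(np.ceil((p - radius - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.floor((p + radius - origin) / spacing).astype(int), shape - 1)
        if np.any(lo > hi):
            n_clipped += 1
            continue
        axes = [
            origin[a] + np.arange(lo[a], hi[a] + 1) * spacing[a] - p[a]
            for a in range(3)
        ]
        if params.norm == 2.0:
            # separable: exp(-(dx^2+dy^2+dz^2)/2s^2) = prod of 1D factors
            f = [np.exp(-(d**2) / (2 * sigma**2)) for d in axes]
            kernel = f[0][:, None, None] * f[1][None, :, None] * f[2][None, None, :]
        else:
            DX, DY, DZ = np.meshgrid(*axes, indexing="ij")
            r = (
                np.abs(DX) ** params.norm
                + np.abs(DY) ** params.norm
                + np.abs(DZ) ** params.norm
            ) ** (1.0 / params.norm)
            kernel = np.exp(-(r**2) / (2 * sigma**2))
        total = kernel.sum()
        if total <= 0:
            n_clipped += 1
            continue
        # per-kernel discrete normalization keeps the kernels exactly
        # equal-weight on the lattice even when bandwidth << grid spacing
        values[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += kernel / total
    if n_clipped:
        logger.warning("%d points fell entirely outside the evaluation grid", n_clipped)

    total = values.sum() * grid.voxel_volume
    if total <= 0:
        raise DensityError("all probability mass fell outside the evaluation grid")
    return DensityMap(grid=grid, values=values / total)


# ---------------------------------------------------------------------------
# level partition and predicted proportions
# ---------------------------------------------------------------------------

def _resample_labels_nearest(levels: LevelLabelVolume, grid: ImageGrid) -> np.ndarray:
    """Nearest-label resample of a level volume onto another grid."""
    if levels.grid.same_geometry(grid):
        return levels.labels
    logger.info(
        "resampling levels from %s to %s by nearest label",
        levels.grid.describe(), grid.describe(),
    )
    centers = grid.all_voxel_centers().reshape(-1, 3)
    vox = round_half_away(levels.grid.world_to_voxel(centers))
    inside = levels.grid.contains_index(vox)
    out = np.zeros(len(centers), dtype=levels.labels.dtype)
    vi = vox[inside]
    out[inside] = levels.labels[vi[:, 0], vi[:, 1], vi[:, 2]]
    return out.reshape(grid.shape)


def level_partition(levels: LevelLabelVolume, grid: ImageGrid) -> np.ndarray:
    """Assign every voxel of *grid* to exactly one level code (1..20).

    Same rule as node assignment: a voxel inside a level keeps that level;
    background voxels go to the level with the nearest foreground voxel
    (per-level Euclidean distance transforms in mm), ties broken by
    canonical level order.
    """
    labels = _resample_labels_nearest(levels, grid)
    codes = sorted(int(c) for c in np.unique(labels) if c != 0)
    if not codes:
        raise DensityError("template level volume has no foreground voxels")
    best = np.full(grid.shape, np.inf)
    winner = np.zeros(grid.shape, dtype=np.int32)
    for code in codes:  # canonical ascending order: strict < keeps the first on ties
        d = ndimage.distance_transform_edt(labels != code, sampling=grid.spacing)
        better = d < best
        winner[better] = code
        best[better] = d[better]
    return winner


@dataclass(frozen=True)
class PredictedDistribution:
    """Per-level probability mass predicted by the density map."""

    proportions: pd.Series  # all 20 levels, canonical order
    residual: float  # mass outside every level cell (0 under the full partition)

    def __post_init__(self) -> None:
        props = self.proportions.reindex(list(LEVEL_NAMES), fill_value=0.0).astype(float)
        if np.any(props.values < -1e-12):
            raise DensityError("proportions must be nonnegative")
        object.__setattr__(self, "proportions", props.clip(lower=0.0))

    @property
    def renormalized(self) -> pd.Series:
        total = float(self.proportions.sum())
        if total <= 0:
            raise DensityError("predicted distribution has no mass on any level")
        return self.proportions / total


def predict_level_proportions(
    density: DensityMap, levels: LevelLabelVolume
) -> PredictedDistribution:
    """Predicted per-level involvement proportions from the density map."""
    partition = level_partition(levels, density.grid)
    mass = density.values * density.grid.voxel_volume
    raw = {}
    for code in np.unique(partition):
        raw[name_for(int(code))] = float(mass[partition == code].sum())
    proportions = pd.Series(raw)
    residual = float(max(0.0, 1.0 - proportions.sum()))
    return PredictedDistribution(proportions=proportions, residual=residual)


# ---------------------------------------------------------------------------
# chi-squared comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    pvalue: float
    n_cells: int


def chisq_compare(observed, predicted, method: str = "gof") -> ChisqResult:
    """Pearson chi-squared comparison of observed counts vs predicted proportions.

    Parameters
    ----------
    observed
        A :class:`nodalmap.assignment.CohortDistribution` or a Series of
        counts indexed by level name.
    predicted
        A :class:`PredictedDistribution` or a Series of proportions.
    method
        ``"gof"`` (default): goodness-of-fit of the observed counts against
        expected counts ``n * p_i`` (cells with zero expectation and zero
        observation dropped; df = cells - 1; no continuity correction).
        ``"homogeneity"``: two-sample chi-squared on the 2 x k table of
        observed counts vs predicted counts.
    """
    obs = (observed.counts if hasattr(observed, "counts") else pd.Series(observed))
    obs = obs.reindex(list(LEVEL_NAMES), fill_value=0).astype(float)
    pred = (
        predicted.renormalized
        if hasattr(predicted, "renormalized")
        else pd.Series(predicted)
    )
    pred = pred.reindex(list(LEVEL_NAMES), fill_value=0.0).astype(float)
    n = float(obs.sum())
    if n <= 0:
        raise DensityError("observed distribution is empty")
    psum = float(pred.sum())
    if psum <= 0:
        raise DensityError("predicted distribution has no mass")
    pred = pred / psum

    expected = pred.values * n
    o = obs.values
    keep = ~((expected < 1e-12) & (o == 0))
    if not keep.any():
        raise DensityError("all cells dropped from the chi-squared comparison")
    o, e = o[keep], expected[keep]

    if method == "gof":
        if np.any(e < 1e-12):
            # observed counts where the prediction puts no mass at all
            return ChisqResult(float("inf"), int(keep.sum() - 1), 0.0, int(keep.sum()))
        statistic = float(((o - e) ** 2 / e).sum())
        df = int(keep.sum() - 1)
        pvalue = float(stats.chi2.sf(statistic, df))
        return ChisqResult(statistic, df, pvalue, int(keep.sum()))
    if method == "homogeneity":
        table = np.vstack([o, e])
        statistic, pvalue, df, _ = stats.chi2_contingency(table, correction=False)
        return ChisqResult(float(statistic), int(df), float(pvalue), int(keep.sum()))
    raise DensityError(f"unknown chi-squared method {method!r}")


def simulate_null_pvalues(
    proportions, n: int, n_replicates: int, seed: int
) -> np.ndarray:
    """Type-I-error simulation: p-values when the observed counts follow the prediction.

    Draws ``n_replicates`` multinomial samples of size *n* from the
    predicted proportions and runs the goodness-of-fit comparison against
    the same proportions.  Under a valid test the rejection rate at any
    alpha approximates alpha.
    """
    pred = pd.Series(proportions).reindex(list(LEVEL_NAMES), fill_value=0.0)
    pred = pred / pred.sum()
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        counts = rng.multinomial(n, pred.values)
        res = chisq_compare(pd.Series(counts, index=pred.index), pred)
        pvals[i] = res.pvalue
    return pvals


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_density(density: DensityMap, path) -> None:
    """Write the density as a NIfTI scalar volume on the template grid."""
    if density.values.sum() <= 0:
        raise DensityError("refusing to export an all-zero density")
    write_scalar_volume(density.values, density.grid, path)


def read_density(path) -> DensityMap:
    values, grid = read_scalar_volume(path)
    return DensityMap(grid=grid, values=values)
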