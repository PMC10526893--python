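"""Assignment of node centers to nodal levels.

A node belongs to the level whose label volume contains its center
(nearest-voxel lookup).  A center in background — outside every level
autosegmentation — is assigned to the *nearest* level, where the distance
from the center to a level is the Euclidean mm distance to that level's
nearest foreground voxel center.  There is no maximum-distance cutoff:
every node receives a level.  Ties are broken by the canonical level
ordering (:data:`nodalmap.levels.LEVEL_NAMES`) and logged.

Distances are computed exactly with one KD-tree per level over the level's
voxel-center coordinates, which agrees with an exhaustive scan over all
foreground voxels up to floating-point round-off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AssignmentError
from .levels import LEVEL_NAMES, name_for
from .volume_io import ASSIGNMENTS_COLUMNS, LevelLabelVolume

logger = logging.getLogger(__name__)

#: Distances within this many mm of the minimum count as tied.
TIE_TOL_MM = 1e-9


@dataclass(frozen=True)
class LevelAssignment:
    """One node -> level decision with diagnostics."""

    level: str
    inside: bool
    distance_mm: float
    runner_up: str
    runner_up_margin_mm: float

    def __post_init__(self) -> None:
        if self.inside and self.distance_mm != 0.0:
            raise AssignmentError("inside assignments must have distance 0")
        if self.distance_mm < 0:
            raise AssignmentError("distance must be >= 0")


class LevelDistanceIndex:
    """Per-level KD-trees over foreground voxel centers of a label volume."""

    def __init__(self, volume: LevelLabelVolume):
        self.volume = volume
        self.grid = volume.grid
        self._trees: dict[str, cKDTree] = {}
        for code in volume.present_codes():
            name = name_for(code)
            idx = np.argwhere(volume.labels == code)
            self._trees[name] = cKDTree(self.grid.voxel_to_world(idx))
        if not self._trees:
            raise AssignmentError("label volume has no foreground voxels")

    @property
    def present_levels(self) -> list[str]:
        """Present level names in canonical order."""
        return [n for n in LEVEL_NAMES if n in self._trees]

    def distances(self, center) -> dict[str, float]:
        """Exact distance (mm) from a point to each present level."""
        center = np.asarray(center, dtype=float)
        return {
            name: float(tree.query(center)[0]) for name, tree in self._trees.items()
        }


def assign_level(
    center, levels: LevelLabelVolume | LevelDistanceIndex
) -> LevelAssignment:
    """Assign one world-mm center to a nodal level.

    Accepts either a label volume or a prebuilt :class:`LevelDistanceIndex`
    (build the index once when assigning many nodes against one volume).
    """
    index = levels if isinstance(levels, LevelDistanceIndex) else LevelDistanceIndex(levels)
    center = np.asarray(center, dtype=float)
    grid = index.grid
    if not bool(grid.contains_point(center)):
        warnings.warn(
            f"center {center.tolist()} lies outside the volume extent; "
            "assigning by nearest level anyway",
            stacklevel=2,
        )

    # containment: nearest-voxel label lookup
    vox = grid.nearest_voxel(center)
    if bool(grid.contains_index(vox)):
        code = int(index.volume.labels[tuple(vox)])
        if code != 0:
            inside_name = name_for(code)
            others = {
                n: d for n, d in index.distances(center).items() if n != inside_name
            }
            if others:
                runner_up = min(others, key=lambda n: (others[n], LEVEL_NAMES.index(n)))
                margin = others[runner_up]
            else:
                runner_up, margin = "", float("inf")
            return LevelAssignment(
                level=inside_name,
                inside=True,
                distance_mm=0.0,
                runner_up=runner_up,
                runner_up_margin_mm=margin,
            )

    dists = index.distances(center)
    ordered = index.present_levels  # canonical order
    dmin = min(dists.values())
    tied = [n for n in ordered if dists[n] <= dmin + TIE_TOL_MM]
    if len(tied) > 1:
        logger.info(
            "tie at %.6f mm between %s; canonical order selects %s",
            dmin, tied, tied[0],
        )
    winner = tied[0]
    rest = [n for n in ordered if n != winner]
    if rest:
        runner_up = min(rest, key=lambda n: (dists[n], LEVEL_NAMES.index(n)))
        margin = dists[runner_up] - dists[winner]
    else:
        runner_up, margin = "", float("inf")
    return LevelAssignment(
        level=winner,
        inside=False,
        distance_mm=dists[winner],
        runner_up=runner_up,
        runner_up_margin_mm=margin,
    )


def assign_level_bruteforce(
    center, volume: LevelLabelVolume
) -> LevelAssignment:
    """Reference implementation: exhaustive scan over every foreground voxel.

    Kept deliberately independent of :func:`assign_level` (no KD-trees) so
    the two can be cross-checked against each other.
    """
    center = np.asarray(center, dtype=float)
    grid = volume.grid
    vox = grid.nearest_voxel(center)
    if bool(grid.contains_index(vox)):
        code = int(volume.labels[tuple(vox)])
        if code != 0:
            name = name_for(code)
            best, bestd = "", float("inf")
            for other in volume.present_codes():
                if other == code:
                    continue
                pts = grid.voxel_to_world(np.argwhere(volume.labels == other))
                d = float(np.min(np.linalg.norm(pts - center, axis=1)))
                if d < bestd:
                    best, bestd = name_for(other), d
            return LevelAssignment(name, True, 0.0, best, bestd)
    codes = volume.present_codes()
    if not codes:
        raise AssignmentError("label volume has no foreground voxels")
    dists = {}
    for code in codes:
        pts = grid.voxel_to_world(np.argwhere(volume.labels == code))
        dists[name_for(code)] = float(np.min(np.linalg.norm(pts - center, axis=1)))
    ordered = [n for n in LEVEL_NAMES if n in dists]
    dmin = min(dists.values())
    winner = next(n for n in ordered if dists[n] <= dmin + TIE_TOL_MM)
    rest = [n for n in ordered if n != winner]
    if rest:
        runner_up = min(rest, key=lambda n: (dists[n], LEVEL_NAMES.index(n)))
        margin = dists[runner_up] - dists[winner]
    else:
        runner_up, margin = "", float("inf")
    return LevelAssignment(winner, False, dists[winner], runner_up, margin)


def assign_cohort(
    nodes: pd.DataFrame, volumes: dict[str, LevelLabelVolume]
) -> tuple[pd.DataFrame, float]:
    """Assign every node in a cohort node table.

    Parameters
    ----------
    nodes
        Node table in the ``nodes.csv`` schema.
    volumes
        Per-patient level label volumes keyed by patient id.

    Returns
    -------
    (assignments, outside_fraction)
        Assignment table in the ``assignments.csv`` schema (same row order
        as *nodes*) and the fraction of nodes outside every level
        autosegmentation (NaN, with a warning, for an empty cohort).
    """
    if len(nodes) == 0:
        warnings.warn("empty node table: outside-fraction undefined", stacklevel=2)
        return pd.DataFrame(columns=ASSIGNMENTS_COLUMNS), float("nan")
    missing = sorted(set(nodes["patient_id"]) - set(volumes))
    if missing:
        raise AssignmentError(f"no level volume for patients {missing}")
    indexes = {
        pid: LevelDistanceIndex(volumes[pid])
        for pid in sorted(set(nodes["patient_id"]))
    }
    rows = []
    for rec in nodes.itertuples(index=False):
        a = assign_level(
            (rec.x_mm, rec.y_mm, rec.z_mm), indexes[rec.patient_id]
        )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "node_id": rec.node_id,
                "level": a.level,
                "inside": a.inside,
                "distance_mm": a.distance_mm,
                "runner_up": a.runner_up,
                "runner_up_margin_mm": a.runner_up_margin_mm,
            }
        )
    out = pd.DataFrame(rows, columns=ASSIGNMENTS_COLUMNS)
    outside_fraction = float((~out["inside"]).mean())
    logger.info(
        "assigned %d nodes; %.1f%% outside level autosegmentations",
        len(out), 100 * outside_fraction,
    )
    return out, outside_fraction


@dataclass(frozen=True)
class CohortDistribution:
    """Per-level involvement counts for a cohort."""

    counts: pd.Series  # indexed by all 20 level names, canonical order

    def __post_init__(self) -> None:
        counts = self.counts.reindex(list(LEVEL_NAMES), fill_value=0).astype(int)
        object.__setattr__(self, "counts", counts)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> pd.Series:
        n = self.n_total
        return self.counts / n if n > 0 else self.counts.astype(float)

    def to_frame(self) -> pd.DataFrame:
        """Table with counts, proportions and 1-decimal percent strings."""
        df = pd.DataFrame(
            {
                "level": self.counts.index,
                "count": self.counts.values,
                "proportion": self.proportions.values,
            }
        )
        df["display"] = [
            f"{c} ({100 * p:.1f}%)" for c, p in zip(df["count"], df["proportion"])
        ]
        return df


def aggregate(levels) -> CohortDistribution:
    """Cohort involvement distribution from assigned level names.

    *levels* may be an assignment table (``level`` column) or any iterable
    of level names; input order is irrelevant.
    """
    if isinstance(levels, pd.DataFrame):
        levels = levels["level"]
    counts = pd.Series(list(levels), dtype=str).value_counts()
    return CohortDistribution(counts=counts)
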