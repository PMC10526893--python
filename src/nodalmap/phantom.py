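"""Synthetic neck-like phantom cohorts with known ground truth.

The phantom emulates the geometry the pipeline consumes — not anatomy or
CT intensities.  A *template* is a label volume of 20 pairwise-disjoint
ellipsoidal level compartments on an anisotropic CT-like grid (default
96x96x64 voxels at 2x2x3 mm, preserving the 3 mm slice thickness typical
of planning CTs), arranged in bilateral columns that are exact mirror
images about the midline sagittal plane, plus a body mask.  A *patient* is
a deformed copy of the template: a random small translation composed with
a Gaussian-smoothed random displacement field (amplitude and smoothness in
mm, invertibility checked), with spherical lymph nodes planted fully
inside their assigned (deformed) level — or deliberately in background for
outside-node stress tests.  The exact patient→template transform used to
generate each patient is retained, so every downstream stage (extraction,
assignment, mapping, density estimation) can be validated against known
ground truth.

Node levels are drawn from a configurable per-level probability vector;
the default emulates a definitive-chemoradiation head-and-neck cohort:
level 2 dominates (~59% bilaterally), followed by level 3, with smaller
contributions from levels 1b, 5, 4a and 8 and none in the remaining
levels.  Per-patient node counts default to uniform 1..6 (cohort mean
~3.5, of the order of the 2-3 metastases per patient seen clinically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PhantomSpecError, PlacementError
from .grid import ImageGrid, round_half_away
from .levels import LEVEL_NAMES, code_for, name_for
from .mapping import DisplacementField, SpatialTransform
from .volume_io import BinaryMask, LevelLabelVolume

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = [
    "patient_id", "node_id", "level",
    "x_mm", "y_mm", "z_mm",          # patient-space center
    "tx_mm", "ty_mm", "tz_mm",       # template-space center (via true transform)
    "radius_mm", "outside",
]

#: Default per-level metastasis probabilities (canonical order keys).
#: Nonzero on the 12 levels commonly involved in definitive-chemoradiation
#: cohorts; heaviest on bilateral level 2, then level 3.
DEFAULT_LEVEL_PROBS: dict[str, float] = {
    "1b_L": 0.04, "1b_R": 0.04,
    "2_L": 0.28, "2_R": 0.30,
    "3_L": 0.11, "3_R": 0.11,
    "4a_L": 0.02, "4a_R": 0.01,
    "5_L": 0.03, "5_R": 0.03,
    "8_L": 0.015, "8_R": 0.015,
}


@dataclass(frozen=True)
class LevelShape:
    """One level compartment: ellipsoid center offset from the grid's
    physical center (mm; x offset signed, +x = right) and semi-axes (mm)."""

    offset_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]


def default_layout() -> dict[str, LevelShape]:
    """Mirror-symmetric default arrangement of the 20 level compartments.

    Bilateral levels sit at x = ±45 mm in two parasagittal columns stacked
    along z (anterior column: 1b/2/3/4a/4b; posterior column: 5/7b/8);
    midline levels (1a/6a/6b/7a) stack on the midsagittal plane.  Gaps of
    >= 3 mm separate neighbouring compartments.
    """
    layout: dict[str, LevelShape] = {}
    # elongated along y so a compartment can hold several non-touching nodes
    r_lat = (14.0, 30.0, 15.0)
    r_mid = (13.0, 25.0, 14.0)
    anterior = {"1b": 65.0, "2": 30.0, "3": -5.0, "4a": -40.0, "4b": -73.0}
    posterior = {"5": 48.0, "7b": 0.0, "8": -48.0}
    for base, dz in anterior.items():
        layout[f"{base}_L"] = LevelShape((-45.0, -33.0, dz), r_lat)
        layout[f"{base}_R"] = LevelShape((45.0, -33.0, dz), r_lat)
    for base, dz in posterior.items():
        layout[f"{base}_L"] = LevelShape((-45.0, 33.0, dz), r_lat)
        layout[f"{base}_R"] = LevelShape((45.0, 33.0, dz), r_lat)
    for name, dz in {"1a": 65.0, "6a": 22.0, "6b": -21.0, "7a": -64.0}.items():
        layout[name] = LevelShape((0.0, -33.0, dz), r_mid)
    return layout


def _default_grid() -> ImageGrid:
    return ImageGrid(shape=(96, 96, 64), spacing=(2.0, 2.0, 3.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of a phantom cohort; deterministic given ``seed``."""

    grid: ImageGrid = field(default_factory=_default_grid)
    layout: dict[str, LevelShape] = field(default_factory=default_layout)
    level_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_PROBS)
    )
    node_radius_mm: tuple[float, float] = (4.0, 10.0)
    deformation_amplitude_mm: float = 4.0
    deformation_smoothness_mm: float = 12.0
    translation_mm: float = 2.0
    nodes_per_patient: tuple[int, int] = (1, 6)
    outside_fraction: float = 0.0
    body_half_size_mm: tuple[float, float, float] = (70.0, 65.0, 92.0)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.layout) - set(LEVEL_NAMES)
        if unknown:
            raise PhantomSpecError(f"layout has unknown levels {sorted(unknown)}")
        unknown = set(self.level_probs) - set(LEVEL_NAMES)
        if unknown:
            raise PhantomSpecError(f"level_probs has unknown levels {sorted(unknown)}")
        total = sum(self.level_probs.values())
        if abs(total - 1.0) > 1e-12:
            raise PhantomSpecError(f"level_probs sum to {total!r}, expected 1")
        if any(p < 0 for p in self.level_probs.values()):
            raise PhantomSpecError("level_probs must be nonnegative")
        lo, hi = self.node_radius_mm
        if not 0 < lo <= hi:
            raise PhantomSpecError("node_radius_mm must satisfy 0 < lo <= hi")
        if self.deformation_amplitude_mm < 0 or self.deformation_smoothness_mm <= 0:
            raise PhantomSpecError("deformation amplitude >= 0 and smoothness > 0 required")
        if not 0 <= self.outside_fraction <= 1:
            raise PhantomSpecError("outside_fraction must be in [0, 1]")
        if not 1 <= self.nodes_per_patient[0] <= self.nodes_per_patient[1]:
            raise PhantomSpecError("nodes_per_patient must satisfy 1 <= lo <= hi")

    @property
    def probs_vector(self) -> np.ndarray:
        return np.array([self.level_probs.get(n, 0.0) for n in LEVEL_NAMES])

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _physical_center(grid: ImageGrid) -> np.ndarray:
    # midpoint of the voxel-center range: mirroring i -> n-1-i reflects
    # voxel centers about this point exactly
    return np.asarray(grid.origin) + (np.asarray(grid.shape) - 1) * np.asarray(
        grid.spacing
    ) / 2.0


def build_template(spec: PhantomSpec) -> tuple[LevelLabelVolume, BinaryMask]:
    """Deterministic template label volume and body mask for a spec.

    All compartments must fit inside the grid and be pairwise disjoint;
    violations raise :class:`PhantomSpecError`.  With the default layout
    the template is exactly mirror symmetric about the midsagittal plane.
    """
    grid = spec.grid
    center = _physical_center(grid)
    axes = [
        np.asarray(grid.origin)[a] + np.arange(grid.shape[a]) * grid.spacing[a]
        for a in range(3)
    ]
    labels = np.zeros(grid.shape, dtype=np.int16)
    extent_lo = np.asarray(grid.origin) - np.asarray(grid.spacing) / 2
    extent_hi = extent_lo + np.asarray(grid.shape) * np.asarray(grid.spacing)
    for name in LEVEL_NAMES:
        shape_def = spec.layout.get(name)
        if shape_def is None:
            continue
        radii = np.asarray(shape_def.radii_mm, dtype=float)
        if np.any(radii < 0):
            raise PhantomSpecError(f"level {name} has negative radii")
        if np.any(radii == 0):
            continue  # zero-size level: absent by request
        c = center + np.asarray(shape_def.offset_mm)
        if np.any(c - radii < extent_lo) or np.any(c + radii > extent_hi):
            raise PhantomSpecError(f"level {name} does not fit inside the grid")
        u = [((axes[a] - c[a]) / radii[a]) ** 2 for a in range(3)]
        mask = (
            u[0][:, None, None] + u[1][None, :, None] + u[2][None, None, :]
        ) <= 1.0
        if np.any(labels[mask] != 0):
            clash = sorted(
                name_for(int(v)) for v in np.unique(labels[mask]) if v != 0
            )
            raise PhantomSpecError(f"level {name} overlaps {clash}")
        labels[mask] = code_for(name)

    half = np.asarray(spec.body_half_size_mm)
    inside = [np.abs(axes[a] - center[a]) <= half[a] for a in range(3)]
    body = (
        inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :]
    )
    if np.any((labels != 0) & ~body):
        raise PhantomSpecError("body mask does not contain all level compartments")
    return (
        LevelLabelVolume(grid=grid, labels=labels),
        BinaryMask(grid=grid, values=body.astype(np.uint8)),
    )


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def sample_transform(spec: PhantomSpec, rng: np.random.Generator) -> SpatialTransform:
    """Random patient→template transform: small translation + smooth field.

    The displacement field is white noise Gaussian-smoothed to the spec's
    smoothness (mm) and rescaled so the maximum displacement magnitude
    equals the amplitude (mm).  Invertibility is checked via the field's
    Jacobian (max Frobenius norm < 0.95); too-aggressive specs raise.
    """
    translation = (
        rng.uniform(-spec.translation_mm, spec.translation_mm, size=3)
        if spec.translation_mm > 0
        else np.zeros(3)
    )
    if spec.deformation_amplitude_mm == 0:
        if not np.any(translation):
            return SpatialTransform.identity()
        return SpatialTransform(translation=translation)

    grid = spec.grid
    sigma_vox = spec.deformation_smoothness_mm / np.asarray(grid.spacing)
    fld = rng.standard_normal(size=grid.shape + (3,)).astype(np.float32)
    for c in range(3):
        fld[..., c] = ndimage.gaussian_filter(fld[..., c], sigma=sigma_vox)
    mag = np.linalg.norm(fld, axis=-1).max()
    if mag > 0:
        fld *= spec.deformation_amplitude_mm / mag

    frob2 = np.zeros(grid.shape)
    for c in range(3):
        for g in np.gradient(fld[..., c], *grid.spacing):
            frob2 += g**2
    jmax = float(np.sqrt(frob2.max()))
    if jmax >= 0.95:
        raise PhantomSpecError(
            f"displacement field not safely invertible (max Jacobian norm {jmax:.2f}); "
            "reduce deformation_amplitude_mm or increase deformation_smoothness_mm"
        )
    return SpatialTransform(
        translation=translation,
        displacement=DisplacementField(grid=grid, values=fld),
    )


def warp_template(
    template: LevelLabelVolume, body: BinaryMask, transform: SpatialTransform
) -> tuple[LevelLabelVolume, BinaryMask]:
    """Patient-space copies of the template volumes under a patient→template map.

    The patient volume is the pull-back of the template through the
    transform: the label at patient voxel x is the template label at the
    mapped point T(x), nearest-voxel lookup.  This makes the generated
    patient geometry exactly consistent with the stored transform.
    """
    import warnings

    grid = template.grid
    centers = grid.all_voxel_centers().reshape(-1, 3)
    with warnings.catch_warnings():
        # voxel centers at the grid edge may map a hair outside the
        # displacement grid; edge clamping is the intended behaviour here
        warnings.simplefilter("ignore", UserWarning)
        mapped = transform.apply(centers)
    vox = round_half_away(grid.world_to_voxel(mapped))
    inside = grid.contains_index(vox)
    vi = vox[inside]
    labels = np.zeros(centers.shape[0], dtype=template.labels.dtype)
    labels[inside] = template.labels[vi[:, 0], vi[:, 1], vi[:, 2]]
    bvals = np.zeros(centers.shape[0], dtype=np.uint8)
    bvals[inside] = body.values[vi[:, 0], vi[:, 1], vi[:, 2]]
    return (
        LevelLabelVolume(grid=grid, labels=labels.reshape(grid.shape)),
        BinaryMask(grid=grid, values=bvals.reshape(grid.shape)),
    )


# ---------------------------------------------------------------------------
# node placement
# ---------------------------------------------------------------------------

def _sphere_offsets(radius_mm: float, spacing) -> np.ndarray:
    """Voxel offsets whose centers lie within radius_mm of the origin (mm)."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    ranges = [np.arange(-h, h + 1) for h in half]
    II, JJ, KK = np.meshgrid(*ranges, indexing="ij")
    d2 = (II * spacing[0]) ** 2 + (JJ * spacing[1]) ** 2 + (KK * spacing[2]) ** 2
    keep = d2 <= radius_mm**2 + 1e-9
    return np.column_stack([II[keep], JJ[keep], KK[keep]])

_MAX_PLACEMENT_ATTEMPTS = 40
_MAX_PATIENT_RESTARTS = 10


class _Placer:
    """Places non-touching spheres inside level compartments of one patient."""

    def __init__(self, labels: LevelLabelVolume, body: BinaryMask):
        self.volume = labels
        self.body = body
        self.grid = labels.grid
        self.occupied = np.zeros(labels.grid.shape, dtype=bool)
        self._edt_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _edt(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        """Interior distance (mm) of a level mask (0 = body background).

        Returns ``(edt, offset)`` where the distance map is cropped to the
        mask's bounding box (plus a 2-voxel zero shell, so distances near
        the crop edge are exact) and *offset* maps crop to global indices.
        """
        if code not in self._edt_cache:
            mask = (
                self.volume.labels == code
                if code > 0
                else (self.body.values.astype(bool) & (self.volume.labels == 0))
            )
            idx = np.argwhere(mask)
            if len(idx) == 0:
                self._edt_cache[code] = (np.zeros((0, 0, 0)), np.zeros(3, dtype=int))
            else:
                lo = np.maximum(idx.min(axis=0) - 2, 0)
                hi = np.minimum(idx.max(axis=0) + 3, np.asarray(self.grid.shape))
                crop = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                edt = ndimage.distance_transform_edt(crop, sampling=self.grid.spacing)
                self._edt_cache[code] = (edt, lo)
        return self._edt_cache[code]

    def place(
        self, code: int, rng: np.random.Generator, radius_range: tuple[float, float]
    ) -> tuple[np.ndarray, float, np.ndarray]:
        """Place one sphere inside level *code* (0 = body background).

        Returns (center world mm, radius mm, sphere voxel indices).  Raises
        :class:`PlacementError` after bounded retries.
        """
        where = "background" if code == 0 else name_for(code)
        edt, offset = self._edt(code)
        spacing = np.asarray(self.grid.spacing)
        lo, hi = radius_range
        if edt.size:
            sl = tuple(
                slice(offset[a], offset[a] + edt.shape[a]) for a in range(3)
            )
            occ = self.occupied[sl]
            occ_dist = (
                ndimage.distance_transform_edt(~occ, sampling=spacing)
                if occ.any()
                else None
            )
        else:
            occ_dist = None
        # keeping centers > r + one voxel diagonal away from occupied voxels
        # guarantees planted spheres stay 26-disconnected
        clearance = float(np.linalg.norm(spacing))
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            # anneal the upper radius bound toward lo so crowded
            # compartments still accept small nodes within bounded retries
            hi_k = max(lo, hi - (hi - lo) * attempt / (_MAX_PLACEMENT_ATTEMPTS - 1))
            radius = float(rng.uniform(lo, hi_k))
            feasible = edt > radius
            if occ_dist is not None:
                feasible &= occ_dist > radius + clearance
            candidates = np.argwhere(feasible)
            if len(candidates) == 0:
                continue
            idx = candidates[rng.integers(len(candidates))] + offset
            sphere = idx + _sphere_offsets(radius, spacing)
            self.occupied[sphere[:, 0], sphere[:, 1], sphere[:, 2]] = True
            return self.grid.voxel_to_world(idx), radius, sphere
        raise PlacementError(
            f"could not place a node in {where} after {_MAX_PLACEMENT_ATTEMPTS} attempts"
        )


@dataclass
class PhantomPatient:
    """One synthetic patient: volumes, planted-node ground truth, true transform."""

    patient_id: str
    seed: int
    truth: pd.DataFrame
    levels: LevelLabelVolume | None = None
    body: BinaryMask | None = None
    gtv: BinaryMask | None = None
    node_masks: list[BinaryMask] | None = None
    transform: SpatialTransform | None = None


def sample_patient(
    template: LevelLabelVolume,
    body: BinaryMask,
    spec: PhantomSpec,
    patient_seed: int,
    patient_id: str = "P000",
    n_nodes: int | None = None,
    outside_flags: list[bool] | None = None,
    keep_volumes: bool = True,
    keep_node_masks: bool = True,
) -> PhantomPatient:
    """Generate one deformed patient with planted nodes and ground truth.

    Ground truth for interior nodes is the planted level.  For requested
    outside (background) nodes the ground-truth level is by definition the
    nearest level in patient space, computed here with the exhaustive
    per-voxel scan so it stays independent of the KD-tree assignment path.
    """
    from .assignment import assign_level_bruteforce

    rng = np.random.default_rng(patient_seed)
    transform = sample_transform(spec, rng)
    if transform.displacement is None and not np.any(transform.translation):
        patient_levels, patient_body = template, body
    else:
        patient_levels, patient_body = warp_template(template, body, transform)

    if n_nodes is None:
        n_nodes = int(rng.integers(spec.nodes_per_patient[0], spec.nodes_per_patient[1] + 1))
    if outside_flags is None:
        outside_flags = (rng.random(n_nodes) < spec.outside_fraction).tolist()
    if len(outside_flags) != n_nodes:
        raise PhantomSpecError("outside_flags length must equal n_nodes")

    # levels are drawn up front from the primary stream, so the pooled level
    # distribution stays exactly multinomial(level_probs) no matter how many
    # placement restarts crowded compartments need below
    probs = spec.probs_vector
    codes = [
        0 if outside_flags[j] else int(rng.choice(len(LEVEL_NAMES), p=probs)) + 1
        for j in range(n_nodes)
    ]

    placements = None
    for restart in range(_MAX_PATIENT_RESTARTS):
        place_rng = np.random.default_rng(
            np.random.SeedSequence([int(patient_seed), restart])
        )
        placer = _Placer(patient_levels, patient_body)
        try:
            placements = [
                placer.place(code, place_rng, spec.node_radius_mm) for code in codes
            ]
            break
        except PlacementError:
            placements = None
    if placements is None:
        raise PlacementError(
            f"could not place {n_nodes} nodes for {patient_id} "
            f"after {_MAX_PATIENT_RESTARTS} restarts (levels "
            f"{[name_for(c) if c else 'background' for c in codes]})"
        )

    gtv = np.zeros(spec.grid.shape, dtype=np.uint8)
    node_masks: list[BinaryMask] = []
    rows = []
    for j, (code, (center, radius, sphere)) in enumerate(zip(codes, placements)):
        level = (
            assign_level_bruteforce(center, patient_levels).level
            if code == 0
            else name_for(code)
        )
        gtv[sphere[:, 0], sphere[:, 1], sphere[:, 2]] = 1
        if keep_node_masks:
            m = np.zeros(spec.grid.shape, dtype=np.uint8)
            m[sphere[:, 0], sphere[:, 1], sphere[:, 2]] = 1
            node_masks.append(BinaryMask(grid=spec.grid, values=m))
        mapped = transform.apply(center)
        rows.append(
            {
                "patient_id": patient_id,
                "node_id": j + 1,
                "level": level,
                "x_mm": center[0], "y_mm": center[1], "z_mm": center[2],
                "tx_mm": mapped[0], "ty_mm": mapped[1], "tz_mm": mapped[2],
                "radius_mm": radius,
                "outside": bool(outside_flags[j]),
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    patient = PhantomPatient(patient_id=patient_id, seed=patient_seed, truth=truth)
    if keep_volumes:
        patient.levels = patient_levels
        patient.body = patient_body
        patient.gtv = BinaryMask(grid=spec.grid, values=gtv)
        patient.transform = transform
        if keep_node_masks:
            patient.node_masks = node_masks
    return patient


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """A phantom cohort: template, patients, pooled ground truth."""

    spec: PhantomSpec
    template_levels: LevelLabelVolume
    template_body: BinaryMask
    patients: list[PhantomPatient]

    @property
    def truth(self) -> pd.DataFrame:
        if not self.patients:
            return pd.DataFrame(columns=TRUTH_COLUMNS)
        return pd.concat([p.truth for p in self.patients], ignore_index=True)

    def transforms(self) -> dict[str, SpatialTransform]:
        """Per-patient true transforms (regenerated from seeds if not kept)."""
        out = {}
        for p in self.patients:
            if p.transform is not None:
                out[p.patient_id] = p.transform
            else:
                out[p.patient_id] = sample_transform(
                    self.spec, np.random.default_rng(p.seed)
                )
        return out

    def gtv_masks(self) -> dict[str, BinaryMask]:
        if any(p.gtv is None for p in self.patients):
            raise PhantomSpecError("cohort was generated with keep_volumes=False")
        return {p.patient_id: p.gtv for p in self.patients}

    def level_volumes(self) -> dict[str, LevelLabelVolume]:
        if any(p.levels is None for p in self.patients):
            raise PhantomSpecError("cohort was generated with keep_volumes=False")
        return {p.patient_id: p.levels for p in self.patients}


def sample_cohort(
    spec: PhantomSpec,
    n_patients: int | None = None,
    total_nodes: int | None = None,
    keep_volumes: bool = True,
) -> CohortBundle:
    """Generate a reproducible cohort.

    Either ``n_patients`` (per-patient node counts uniform in
    ``spec.nodes_per_patient``) or ``total_nodes`` (patients generated
    until the pooled node count is exact) must be given.  When
    ``spec.outside_fraction`` > 0, exactly ``round(fraction * total)``
    nodes are planted in background, chosen by a seeded permutation.
    """
    if (n_patients is None) == (total_nodes is None):
        raise PhantomSpecError("specify exactly one of n_patients or total_nodes")
    template_levels, template_body = build_template(spec)
    master = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0F0]))
    lo, hi = spec.nodes_per_patient

    counts: list[int] = []
    if n_patients is not None:
        counts = [int(master.integers(lo, hi + 1)) for _ in range(n_patients)]
    else:
        while sum(counts) < total_nodes:
            counts.append(min(int(master.integers(lo, hi + 1)), total_nodes - sum(counts)))
    total = sum(counts)

    flags = np.zeros(total, dtype=bool)
    n_outside = int(round(spec.outside_fraction * total))
    if n_outside:
        flags[master.permutation(total)[:n_outside]] = True

    ss = np.random.SeedSequence([spec.seed, 0x5EED])
    child_seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(len(counts))]
    patients = []
    offset = 0
    width = max(3, len(str(max(len(counts), 1))))
    for i, (n_nodes, child) in enumerate(zip(counts, child_seeds)):
        patient = sample_patient(
            template_levels,
            template_body,
            spec,
            patient_seed=child,
            patient_id=f"P{i:0{width}d}",
            n_nodes=n_nodes,
            outside_flags=flags[offset : offset + n_nodes].tolist(),
            keep_volumes=keep_volumes,
            keep_node_masks=False,
        )
        offset += n_nodes
        patients.append(patient)
    logger.info(
        "phantom cohort: %d patients, %d nodes (%d outside)",
        len(patients), total, n_outside,
    )
    return CohortBundle(
        spec=spec,
        template_levels=template_levels,
        template_body=template_body,
        patients=patients,
    )
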