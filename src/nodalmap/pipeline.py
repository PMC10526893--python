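"""End-to-end orchestration: manifests in, tables/volumes/report out.

A run consumes per-patient manifests (CSV listing file paths), executes
extract → assign → (review) → map → density → compare, and writes
per-stage artifacts as plain files into a run directory so stages can also
be re-run independently.  Every output directory gets a ``provenance.json``
(package version, config hash, seed); rerunning an identical config
reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assignment import aggregate, assign_cohort
from .density import (
    DensityParams,
    chisq_compare,
    estimate_density,
    export_density,
    predict_level_proportions,
)
from .errors import ConfigurationError, NodalMapError
from .extraction import ExtractionParams, extract_cohort_nodes
from .grid import isotropic_like
from .mapping import SpatialTransform, map_cohort
from .phantom import CohortBundle
from .review import majority_distribution, reader_agreement
from .volume_io import (
    TABLE_SCHEMA_VERSION,
    read_binary_mask,
    read_label_volume,
    read_votes_csv,
    write_assignments_csv,
    write_binary_mask,
    write_distribution_csv,
    write_label_volume,
    write_mapped_csv,
    write_nodes_csv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run (JSON-serializable)."""

    out_dir: str
    masks_manifest: str
    levels_manifest: str
    transforms_manifest: str | None = None
    votes_csv: str | None = None
    template_levels: str | None = None
    template_body: str | None = None
    extraction: dict = field(default_factory=dict)
    density: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("masks_manifest", "levels_manifest", "transforms_manifest",
                     "votes_csv", "template_levels", "template_body"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name} path does not exist: {value}")

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def write_provenance(out_dir, config_digest: str, seed: int) -> None:
    payload = {
        "package": "nodalmap",
        "version": __version__,
        "table_schema_version": TABLE_SCHEMA_VERSION,
        "config_sha256": config_digest,
        "seed": seed,
    }
    with open(Path(out_dir) / "provenance.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


@contextmanager
def _stage(name: str):
    try:
        logger.info("stage %s: start", name)
        yield
        logger.info("stage %s: done", name)
    except NodalMapError as err:
        raise type(err)(f"stage {name!r} failed: {err}") from err


def _read_manifest(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: manifest missing columns {missing}")
    return df


def load_transforms(manifest_path) -> dict[str, SpatialTransform]:
    df = _read_manifest(manifest_path, ["patient_id", "affine_path"])
    out = {}
    for rec in df.itertuples(index=False):
        disp = getattr(rec, "displacement_path", "") or None
        out[rec.patient_id] = SpatialTransform.from_files(rec.affine_path, disp)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary report dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"n_patients": None, "n_nodes": None}

    with _stage("extract"):
        manifest = _read_manifest(config.masks_manifest, ["patient_id", "mask_path"])
        masks = {r.patient_id: read_binary_mask(r.mask_path) for r in manifest.itertuples(index=False)}
        nodes = extract_cohort_nodes(masks, ExtractionParams(**config.extraction))
        write_nodes_csv(nodes, out / "nodes.csv")
        report["n_patients"] = len(masks)
        report["n_nodes"] = len(nodes)

    with _stage("assign"):
        manifest = _read_manifest(config.levels_manifest, ["patient_id", "levels_path"])
        volumes = {r.patient_id: read_label_volume(r.levels_path) for r in manifest.itertuples(index=False)}
        assignments, outside_fraction = assign_cohort(nodes, volumes)
        write_assignments_csv(assignments, out / "assignments.csv")
        distribution = aggregate(assignments)
        write_distribution_csv(distribution.to_frame(), out / "distribution.csv")
        report["outside_fraction"] = outside_fraction
        report["counts"] = distribution.counts.to_dict()

    if config.votes_csv is not None:
        with _stage("review"):
            votes = read_votes_csv(config.votes_csv)
            consensus, agreement = majority_distribution(assignments, votes)
            per_reader, columns = reader_agreement(assignments, votes)
            write_distribution_csv(consensus.to_frame(), out / "consensus_distribution.csv")
            columns.to_csv(out / "reader_columns.csv", lineterminator="\n")
            report["majority_agreement"] = agreement
            report["reader_agreement"] = per_reader.to_dict()

    mapped = None
    if config.transforms_manifest is not None:
        with _stage("map"):
            transforms = load_transforms(config.transforms_manifest)
            body = (
                read_binary_mask(config.template_body)
                if config.template_body is not None
                else None
            )
            mapped = map_cohort(nodes, transforms, template_body=body)
            write_mapped_csv(mapped, out / "mapped.csv")
            report["n_mapped"] = len(mapped)

    if mapped is not None and config.template_levels is not None:
        with _stage("density"):
            params = DensityParams(**config.density)
            template = read_label_volume(config.template_levels)
            eval_grid = isotropic_like(template.grid, params.grid_spacing_mm)
            density = estimate_density(
                mapped[["x_mm", "y_mm", "z_mm"]].to_numpy(), eval_grid, params
            )
            export_density(density, out / "density.nii.gz")
            predicted = predict_level_proportions(density, template)
            pred_df = pd.DataFrame(
                {
                    "level": predicted.proportions.index,
                    "count": np.round(predicted.proportions.values * len(mapped)).astype(int),
                    "proportion": predicted.proportions.values,
                }
            )
            write_distribution_csv(pred_df, out / "predicted_distribution.csv")
            result = chisq_compare(distribution, predicted)
            report["chisq"] = {
                "statistic": result.statistic,
                "df": result.df,
                "pvalue": result.pvalue,
            }
            with open(out / "chisq.json", "w") as fh:
                json.dump(report["chisq"], fh, indent=2, sort_keys=True)
                fh.write("\n")

    write_provenance(out, config.digest(), config.seed)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# phantom cohort export
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, out_dir) -> dict[str, str]:
    """Write a phantom cohort as pipeline-consumable files.

    Emits template volumes, per-patient level/GTV volumes, transform file
    pairs, the pooled ground-truth table and the three stage manifests.
    Requires a cohort generated with ``keep_volumes=True``.
    """
    out = Path(out_dir)
    (out / "patients").mkdir(parents=True, exist_ok=True)
    write_label_volume(bundle.template_levels, out / "template_levels.nii.gz")
    write_binary_mask(bundle.template_body, out / "template_body.nii.gz")
    bundle.truth.to_csv(out / "truth.csv", index=False, lineterminator="\n")

    masks_rows, levels_rows, transform_rows = [], [], []
    transforms = bundle.transforms()
    for patient in bundle.patients:
        if patient.levels is None or patient.gtv is None:
            raise ConfigurationError("cohort was generated with keep_volumes=False")
        pdir = out / "patients" / patient.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        write_label_volume(patient.levels, pdir / "levels.nii.gz")
        write_binary_mask(patient.gtv, pdir / "gtv.nii.gz")
        transform = transforms[patient.patient_id]
        affine_path = pdir / "affine.txt"
        disp_path = pdir / "displacement.nii.gz" if transform.displacement is not None else None
        transform.to_files(affine_path, disp_path)
        masks_rows.append({"patient_id": patient.patient_id, "mask_path": str(pdir / "gtv.nii.gz")})
        levels_rows.append({"patient_id": patient.patient_id, "levels_path": str(pdir / "levels.nii.gz")})
        transform_rows.append(
            {
                "patient_id": patient.patient_id,
                "affine_path": str(affine_path),
                "displacement_path": str(disp_path) if disp_path else "",
            }
        )
    paths = {
        "masks_manifest": str(out / "masks_manifest.csv"),
        "levels_manifest": str(out / "levels_manifest.csv"),
        "transforms_manifest": str(out / "transforms_manifest.csv"),
        "template_levels": str(out / "template_levels.nii.gz"),
        "template_body": str(out / "template_body.nii.gz"),
        "truth": str(out / "truth.csv"),
    }
    pd.DataFrame(masks_rows).to_csv(paths["masks_manifest"], index=False, lineterminator="\n")
    pd.DataFrame(levels_rows).to_csv(paths["levels_manifest"], index=False, lineterminator="\n")
    pd.DataFrame(transform_rows).to_csv(paths["transforms_manifest"], index=False, lineterminator="\n")
    return paths
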