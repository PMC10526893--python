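"""Phantom generator: template geometry, determinism, sampling distributions."""

import numpy as np
import pytest
from dataclasses import replace

from nodalmap.errors import PhantomSpecError
from nodalmap.levels import LEVEL_NAMES, code_for, mirror_name
from nodalmap.phantom import (
    LevelShape,
    PhantomSpec,
    build_template,
    default_layout,
    sample_cohort,
    sample_patient,
    sample_transform,
)


def test_template_disjoint_mirror_symmetric(default_spec, template):
    levels, body = template
    assert levels.present_codes() == list(range(1, 21))
    # mirror symmetry: flipping the x axis swaps _L and _R masks exactly
    for name in LEVEL_NAMES:
        flipped = np.flip(levels.labels == code_for(name), axis=0)
        assert np.array_equal(flipped, levels.labels == code_for(mirror_name(name)))
    # all compartments inside the body
    assert not np.any((levels.labels != 0) & (body.values == 0))


def test_template_deterministic(default_spec):
    a, _ = build_template(default_spec)
    b, _ = build_template(default_spec)
    assert np.array_equal(a.labels, b.labels)


def test_template_scaling_one_level():
    """Scaling one compartment's volume by 2 roughly doubles its voxel count
    and leaves every other compartment untouched."""
    spec = PhantomSpec()
    layout = default_layout()
    shape = layout["2_R"]
    factor = 2.0 ** (1.0 / 3.0)
    layout["2_R"] = LevelShape(
        shape.offset_mm, tuple(r * factor for r in shape.radii_mm)
    )
    base, _ = build_template(spec)
    grown, _ = build_template(
        replace(spec, layout=layout, body_half_size_mm=(70.0, 80.0, 92.0))
    )
    code = code_for("2_R")
    ratio = (grown.labels == code).sum() / (base.labels == code).sum()
    assert ratio == pytest.approx(2.0, rel=0.1)
    for name in LEVEL_NAMES:
        if name == "2_R":
            continue
        assert np.array_equal(
            grown.labels == code_for(name), base.labels == code_for(name)
        )


def test_overlapping_layout_rejected():
    layout = default_layout()
    layout["2_R"] = LevelShape((45.0, -33.0, 60.0), (14.0, 30.0, 15.0))  # into 1b_R
    with pytest.raises(PhantomSpecError, match="overlaps"):
        build_template(PhantomSpec(layout=layout))


def test_bad_probs_rejected():
    with pytest.raises(PhantomSpecError, match="sum to"):
        PhantomSpec(level_probs={"2_R": 0.5})


def test_zero_amplitude_is_identity(template):
    spec = PhantomSpec(seed=3, deformation_amplitude_mm=0.0, translation_mm=0.0)
    levels, body = template
    patient = sample_patient(levels, body, spec, patient_seed=1, n_nodes=2)
    assert np.array_equal(patient.levels.labels, levels.labels)
    assert patient.transform.displacement is None


def test_excessive_deformation_rejected():
    spec = PhantomSpec(deformation_amplitude_mm=40.0, deformation_smoothness_mm=4.0)
    with pytest.raises(PhantomSpecError, match="invertible"):
        sample_transform(spec, np.random.default_rng(0))


def test_one_hot_probs_all_nodes_in_that_level(default_spec, template):
    # smaller radii so ten non-touching nodes fit in a single compartment
    levels, body = template
    spec = replace(default_spec, level_probs={"3_L": 1.0}, node_radius_mm=(4.0, 5.0))
    patient = sample_patient(levels, body, spec, patient_seed=8, n_nodes=10)
    assert patient.truth["level"].tolist() == ["3_L"] * 10


def test_nodes_fully_inside_assigned_level(default_spec, template):
    levels, body = template
    patient = sample_patient(levels, body, default_spec, patient_seed=17, n_nodes=5)
    for mask, rec in zip(patient.node_masks, patient.truth.itertuples(index=False)):
        covered = patient.levels.labels[mask.values.astype(bool)]
        assert (covered == code_for(rec.level)).all()


def test_cohort_determinism_and_bounds():
    spec = PhantomSpec(seed=5, deformation_amplitude_mm=0.0, translation_mm=0.0)
    a = sample_cohort(spec, n_patients=6, keep_volumes=False)
    b = sample_cohort(spec, n_patients=6, keep_volumes=False)
    assert a.truth.equals(b.truth)
    lo, hi = spec.nodes_per_patient
    per_patient = a.truth.groupby("patient_id").size()
    assert per_patient.between(lo, hi).all()

    empty = sample_cohort(spec, n_patients=0)
    assert len(empty.truth) == 0 and len(empty.patients) == 0


def test_transforms_regenerated_from_seeds_match():
    spec = PhantomSpec(seed=6)
    kept = sample_cohort(spec, n_patients=2, keep_volumes=True)
    slim = sample_cohort(spec, n_patients=2, keep_volumes=False)
    p = np.array([80.0, 90.0, 100.0])
    for pid, t in kept.transforms().items():
        assert np.allclose(slim.transforms()[pid].apply(p), t.apply(p), atol=1e-12)


def test_pooled_level_counts_follow_probs():
    """Pooled ground-truth counts are within 3 binomial SD of n*p per level
    (multinomial sampling check on an undeformed cohort)."""
    spec = PhantomSpec(seed=9, deformation_amplitude_mm=0.0, translation_mm=0.0)
    bundle = sample_cohort(spec, n_patients=100, keep_volumes=False)
    truth = bundle.truth
    n = len(truth)
    counts = truth["level"].value_counts()
    for name in LEVEL_NAMES:
        p = spec.level_probs.get(name, 0.0)
        observed = counts.get(name, 0)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) <= max(3 * sd, 1e-9), name


def test_outside_nodes_exact_count_and_background():
    spec = PhantomSpec(seed=12, outside_fraction=41 / 449)
    bundle = sample_cohort(spec, total_nodes=100, keep_volumes=True)
    truth = bundle.truth
    assert len(truth) == 100
    assert int(truth["outside"].sum()) == round(41 / 449 * 100)
    for patient in bundle.patients:
        for rec in patient.truth.itertuples(index=False):
            vox = patient.levels.grid.nearest_voxel((rec.x_mm, rec.y_mm, rec.z_mm))
            label = patient.levels.labels[tuple(vox)]
            assert (label == 0) == rec.outside
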