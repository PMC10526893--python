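"""Level assignment: containment, nearest-level distances, ties, aggregation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_label_volume, make_sphere_mask
from nodalmap.assignment import (
    aggregate,
    assign_cohort,
    assign_level,
    assign_level_bruteforce,
)
from nodalmap.errors import AssignmentError
from nodalmap.grid import ImageGrid
from nodalmap.levels import LEVEL_NAMES, code_for
from nodalmap.volume_io import LevelLabelVolume


@pytest.fixture
def two_cuboids():
    """Level 2_L occupies x-index 2..3, level 2_R x-index 12..13 (1 mm grid)."""
    grid = ImageGrid(shape=(16, 8, 8), spacing=(1.0, 1.0, 1.0))
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[2:4, 2:6, 2:6] = code_for("2_L")
    labels[12:14, 2:6, 2:6] = code_for("2_R")
    return LevelLabelVolume(grid=grid, labels=labels)


def test_containment_inside_level(two_cuboids):
    a = assign_level((3.0, 4.0, 4.0), two_cuboids)
    assert (a.level, a.inside, a.distance_mm) == ("2_L", True, 0.0)


def test_nearest_level_distance_constructed(two_cuboids):
    """Center at x=6 in background: 2_L's nearest voxel is 3 mm away, 2_R's 6 mm."""
    a = assign_level((6.0, 4.0, 4.0), two_cuboids)
    assert a.level == "2_L" and not a.inside
    assert a.distance_mm == pytest.approx(3.0, abs=1e-12)
    assert a.runner_up == "2_R"
    assert a.runner_up_margin_mm == pytest.approx(3.0, abs=1e-12)


def test_midline_tie_goes_to_canonical_first(two_cuboids):
    """Exactly equidistant between mirrored levels: canonical order (_L first)."""
    a = assign_level((7.5, 4.0, 4.0), two_cuboids)
    assert a.level == "2_L" and a.distance_mm == pytest.approx(4.5)


def test_point_outside_extent_still_assigned(two_cuboids):
    with pytest.warns(UserWarning, match="outside the volume extent"):
        a = assign_level((-30.0, 4.0, 4.0), two_cuboids)
    assert a.level == "2_L"


def test_empty_label_volume_rejected():
    grid = ImageGrid(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0))
    empty = LevelLabelVolume(grid=grid, labels=np.zeros(grid.shape, dtype=np.int16))
    with pytest.raises(AssignmentError, match="no foreground"):
        assign_level((4.0, 4.0, 4.0), empty)


def _random_volume(rng) -> LevelLabelVolume:
    """Small random label volume: a few random blobs on an anisotropic grid."""
    grid = ImageGrid(shape=(12, 12, 8), spacing=(1.5, 1.5, 3.0))
    labels = np.zeros(grid.shape, dtype=np.int16)
    n_levels = rng.integers(2, 6)
    codes = rng.choice(20, size=n_levels, replace=False) + 1
    for code in codes:
        c = rng.uniform([0, 0, 0], np.asarray(grid.extent_mm))
        r = rng.uniform(2.0, 6.0)
        labels[make_sphere_mask(grid, c, r) & (labels == 0)] = code
    return LevelLabelVolume(grid=grid, labels=labels)


def test_oracle_equivalence_random_instances():
    """KD-tree assignment agrees with the exhaustive per-voxel scan on random
    (center, label-volume) instances — winner, containment and distance."""
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 300:
        volume = _random_volume(rng)
        if not volume.present_codes():
            continue
        for _ in range(10):
            center = rng.uniform([-3, -3, -3], np.asarray(volume.grid.extent_mm) + 3)
            fast = assign_level(center, volume)
            slow = assign_level_bruteforce(center, volume)
            assert fast.level == slow.level
            assert fast.inside == slow.inside
            assert fast.distance_mm == pytest.approx(slow.distance_mm, abs=1e-9)
            checked += 1


def test_constructed_exact_tie_agrees_with_oracle(two_cuboids):
    """Tie handling is identical in both implementations on exact midline ties."""
    for y in (3.0, 4.5):
        fast = assign_level((7.5, y, 4.0), two_cuboids)
        slow = assign_level_bruteforce((7.5, y, 4.0), two_cuboids)
        assert fast.level == slow.level == "2_L"


def test_winner_stable_under_winning_level_dilation(two_cuboids):
    """Dilating the winning level's mask can only keep (or strengthen) the win."""
    from scipy import ndimage

    a = assign_level((6.0, 4.0, 4.0), two_cuboids)
    grown = two_cuboids.labels.copy()
    mask = ndimage.binary_dilation(grown == code_for("2_L"))
    grown[mask & (grown == 0)] = code_for("2_L")
    b = assign_level((6.0, 4.0, 4.0), LevelLabelVolume(grid=two_cuboids.grid, labels=grown))
    assert b.level == a.level
    assert b.distance_mm <= a.distance_mm


def test_assign_cohort_outside_fraction(two_cuboids):
    nodes = pd.DataFrame(
        {
            "patient_id": ["P0"] * 4,
            "node_id": [1, 2, 3, 4],
            "x_mm": [3.0, 13.0, 6.0, 8.0],
            "y_mm": [4.0] * 4,
            "z_mm": [4.0] * 4,
            "voxel_count": [1] * 4,
            "component_id": [1, 2, 3, 4],
        }
    )
    assignments, outside = assign_cohort(nodes, {"P0": two_cuboids})
    assert outside == pytest.approx(0.5)
    assert assignments["level"].tolist() == ["2_L", "2_R", "2_L", "2_R"]

    with pytest.warns(UserWarning, match="empty node table"):
        empty, frac = assign_cohort(nodes.iloc[:0], {"P0": two_cuboids})
    assert len(empty) == 0 and np.isnan(frac)


def test_aggregate_counts_and_order_invariance():
    levels = ["2_R"] * 3 + ["2_L"] * 2 + ["7a"]
    dist = aggregate(levels)
    assert dist.n_total == 6
    assert dist.counts["2_R"] == 3 and dist.counts["1a"] == 0
    assert dist.proportions.sum() == pytest.approx(1.0, abs=1e-12)
    shuffled = aggregate(levels[::-1])
    assert dist.counts.equals(shuffled.counts)
    assert list(dist.counts.index) == list(LEVEL_NAMES)

    single = aggregate(["5_L"])
    assert single.proportions["5_L"] == 1.0
    row = single.to_frame().set_index("level").loc["5_L"]
    assert row["display"] == "1 (100.0%)"
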