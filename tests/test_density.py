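"""Kernel density estimation, level-proportion prediction, chi-squared test."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_label_volume
from nodalmap.assignment import CohortDistribution, aggregate
from nodalmap.density import (
    DensityParams,
    chisq_compare,
    estimate_density,
    export_density,
    level_partition,
    predict_level_proportions,
    read_density,
    simulate_null_pvalues,
)
from nodalmap.errors import DensityError
from nodalmap.grid import ImageGrid
from nodalmap.levels import code_for


@pytest.fixture
def eval_grid():
    return ImageGrid(shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0))


def gaussian_mixture_pdf(x, centers, sigma):
    """Closed-form equal-weight isotropic Gaussian mixture density."""
    x = np.asarray(x, dtype=float)
    norm = (2 * np.pi * sigma**2) ** 1.5
    vals = [
        np.exp(-np.sum((x - c) ** 2) / (2 * sigma**2)) / norm for c in centers
    ]
    return sum(vals) / len(vals)


def test_single_point_unimodal_normalized(eval_grid):
    p = np.array([41.3, 38.6, 40.0])
    d = estimate_density([p], eval_grid, DensityParams(bandwidth_mm=4.0))
    assert d.integral == pytest.approx(1.0, abs=1e-6)
    argmax = np.unravel_index(np.argmax(d.values), d.values.shape)
    assert np.array_equal(argmax, eval_grid.nearest_voxel(p))


def test_two_point_mixture_matches_closed_form(eval_grid):
    """KDE values at voxel centers match the analytic two-component Gaussian
    mixture within discretization error (points 20 mm apart, bandwidth 4)."""
    centers = [np.array([30.0, 40.0, 40.0]), np.array([50.0, 40.0, 40.0])]
    d = estimate_density(centers, eval_grid, DensityParams(bandwidth_mm=4.0))
    rng = np.random.default_rng(0)
    probes = np.vstack([centers, rng.uniform(20, 60, size=(20, 3))])
    for x in probes:
        vox = tuple(eval_grid.nearest_voxel(x))
        x_grid = eval_grid.voxel_to_world(vox)
        expected = gaussian_mixture_pdf(x_grid, centers, 4.0)
        assert d.values[vox] == pytest.approx(expected, rel=1e-3, abs=1e-12)


def test_mirror_symmetric_points_give_symmetric_density(eval_grid):
    pts = np.array(
        [[39.0 - 10, 30.0, 30.0], [39.0 + 10, 30.0, 30.0],
         [39.0 - 4, 50.0, 44.0], [39.0 + 4, 50.0, 44.0]]
    )  # mirror plane x = 39 = voxel-center midplane
    d = estimate_density(pts, eval_grid, DensityParams(bandwidth_mm=4.0))
    assert np.max(np.abs(d.values - np.flip(d.values, axis=0))) < 1e-9


def test_general_p_norm_kernel(eval_grid):
    """p = 1 kernel is broader along diagonals but still normalized."""
    p = np.array([40.0, 40.0, 40.0])
    d = estimate_density([p], eval_grid, DensityParams(bandwidth_mm=4.0, norm=1.0))
    assert d.integral == pytest.approx(1.0, abs=1e-6)
    on_axis = d.values[tuple(eval_grid.nearest_voxel(p + [4, 0, 0]))]
    diagonal = d.values[tuple(eval_grid.nearest_voxel(p + [4, 4, 0]))]
    assert diagonal < on_axis  # |.|_1 grows faster off-axis


def test_degenerate_inputs_rejected(eval_grid):
    with pytest.raises(DensityError, match="at least one point"):
        estimate_density(np.empty((0, 3)), eval_grid)
    with pytest.raises(DensityError, match="bandwidth"):
        DensityParams(bandwidth_mm=0.0)


def test_density_entirely_inside_one_level(eval_grid):
    region = np.zeros(eval_grid.shape, dtype=bool)
    region[10:30, 10:30, 10:30] = True
    levels = make_label_volume(eval_grid, {code_for("2_R"): region})
    d = estimate_density([[40.0, 40.0, 40.0]], eval_grid, DensityParams(bandwidth_mm=2.0))
    pred = predict_level_proportions(d, levels)
    assert pred.proportions["2_R"] == pytest.approx(1.0, abs=1e-9)
    assert pred.residual == pytest.approx(0.0, abs=1e-9)


def test_uniform_density_splits_by_voxel_count():
    """Uniform mass over a region split 70/30 between two levels by voxel
    count yields proportions 0.7/0.3."""
    grid = ImageGrid(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0))
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[:7] = code_for("2_L")
    labels[7:] = code_for("2_R")
    levels = make_label_volume(grid, {code_for("2_L"): labels == code_for("2_L"),
                                      code_for("2_R"): labels == code_for("2_R")})
    from nodalmap.density import DensityMap

    uniform = DensityMap(grid=grid, values=np.full(grid.shape, 1.0 / 1000.0))
    pred = predict_level_proportions(uniform, levels)
    assert pred.proportions["2_L"] == pytest.approx(0.7, abs=1e-9)
    assert pred.proportions["2_R"] == pytest.approx(0.3, abs=1e-9)


def test_partition_matches_node_assignment_rule():
    """Voxel partition agrees with per-point nearest-level assignment."""
    from nodalmap.assignment import assign_level

    grid = ImageGrid(shape=(12, 8, 8), spacing=(2.0, 2.0, 2.0))
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[1:3, 2:6, 2:6] = code_for("3_L")
    labels[9:11, 2:6, 2:6] = code_for("3_R")
    levels = make_label_volume(grid, {code_for("3_L"): labels == code_for("3_L"),
                                      code_for("3_R"): labels == code_for("3_R")})
    part = level_partition(levels, grid)
    rng = np.random.default_rng(5)
    for idx in rng.integers(0, grid.shape, size=(40, 3)):
        center = grid.voxel_to_world(idx)
        assert part[tuple(idx)] == code_for(assign_level(center, levels).level)


def test_chisq_hand_computed_case():
    """Observed (10,20,70) vs predicted (0.2,0.2,0.6), n=100: X2=6.667, df=2."""
    observed = pd.Series({"2_L": 10, "2_R": 20, "3_L": 70})
    predicted = pd.Series({"2_L": 0.2, "2_R": 0.2, "3_L": 0.6})
    res = chisq_compare(observed, predicted)
    assert res.statistic == pytest.approx(20 / 3, rel=1e-9)
    assert res.df == 2
    from scipy.stats import chi2

    assert res.pvalue == pytest.approx(float(chi2.sf(20 / 3, 2)), rel=1e-12)


def test_chisq_exact_match_gives_p_one():
    observed = pd.Series({"2_L": 30, "2_R": 60, "3_L": 10})
    predicted = pd.Series({"2_L": 0.3, "2_R": 0.6, "3_L": 0.1})
    res = chisq_compare(observed, predicted)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_chisq_drops_jointly_empty_cells():
    observed = CohortDistribution(counts=pd.Series({"2_L": 50, "2_R": 50}))
    predicted = pd.Series({"2_L": 0.5, "2_R": 0.5})
    res = chisq_compare(observed, predicted)
    assert res.n_cells == 2 and res.df == 1

    res2 = chisq_compare(observed, predicted, method="homogeneity")
    assert res2.pvalue == pytest.approx(1.0)


def test_chisq_empty_observed_rejected():
    with pytest.raises(DensityError, match="empty"):
        chisq_compare(pd.Series(dtype=float), pd.Series({"2_L": 1.0}))


def test_null_pvalues_close_to_uniform_small():
    pvals = simulate_null_pvalues(
        pd.Series({"2_L": 0.4, "2_R": 0.4, "3_L": 0.2}), n=200, n_replicates=200, seed=7
    )
    # crude uniformity check; the full calibration lives in the acceptance suite
    assert 0.01 < (pvals < 0.5).mean() < 0.75


def test_export_round_trip(tmp_path, eval_grid):
    d = estimate_density([[40.0, 40.0, 40.0]], eval_grid, DensityParams())
    export_density(d, tmp_path / "density.nii.gz")
    back = read_density(tmp_path / "density.nii.gz")
    assert back.grid.same_geometry(eval_grid, tol=1e-5)
    assert np.allclose(back.values, d.values, atol=1e-9)
    assert back.integral == pytest.approx(1.0, abs=1e-5)
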