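"""Partitioned Mahalanobis habitat model: bootstrap, fit, scoring, validation."""

import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from kinscape import (EnvGrid, Grid, HabitatModel, OccurrenceSet,
                      SimulationSpec, fit_partitioned_d2, score_hsi,
                      simulate_landscape, spatial_bootstrap,
                      threshold_suitability, thin_occurrences, validate_model)
from kinscape.habitat import default_partition, hsi_from_d2, mahalanobis_d2


def _env_pair(seed=0, n=40):
    """Two-variable EnvGrid with standard-normal independent layers."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, n))
    b = rng.standard_normal((n, n))
    return EnvGrid({"a": Grid(a, 0, 0, 150.0), "b": Grid(b, 0, 0, 150.0)})


def _occ(points, areas=None):
    pts = np.asarray(points, float)
    areas = areas if areas is not None else ["x"] * len(pts)
    return OccurrenceSet(pts, np.asarray(areas))


# ---------------------------------------------------------------------------
# Spatial bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_below_cap_keeps_all():
    occ = _occ([(100 + 150 * i, 100) for i in range(30)])
    subsets = list(spatial_bootstrap(occ, cap=50, iterations=3, seed=0))
    assert all(len(s) == 30 for s in subsets)


def test_bootstrap_cap_binds_and_varies():
    occ = _occ([(100 + 30 * i, 100) for i in range(200)])
    subsets = [s.points[:, 0] for s in
               spatial_bootstrap(occ, cap=50, iterations=5, seed=1)]
    assert all(len(s) == 50 for s in subsets)
    assert any(not np.array_equal(subsets[0], s) for s in subsets[1:])


def test_bootstrap_deterministic():
    occ = _occ([(10 * i, 5) for i in range(100)])
    a = [s.points for s in spatial_bootstrap(occ, cap=20, iterations=4, seed=9)]
    b = [s.points for s in spatial_bootstrap(occ, cap=20, iterations=4, seed=9)]
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_bootstrap_empty_errors():
    with pytest.raises(ValueError):
        next(spatial_bootstrap(_occ(np.empty((0, 2))), iterations=1, seed=0))


def test_thin_occurrences_one_per_cell():
    g = Grid(np.zeros((4, 4)), 0, 0, 150.0)
    occ = _occ([(10, 10), (20, 20), (200, 10)])
    thinned = thin_occurrences(occ, g)
    assert len(thinned) == 2


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def test_identical_subsets_equal_single_pca_fit():
    env = _env_pair(3)
    rng = np.random.default_rng(4)
    pts = np.column_stack([rng.uniform(10, 5900, 50), rng.uniform(10, 5900, 50)])
    occ = _occ(pts)
    model = fit_partitioned_d2(iter([occ] * 5), env)
    x = env.extract(pts)
    mu, sd = x.mean(0), x.std(0, ddof=1)
    corr = np.corrcoef((x - mu) / sd, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    assert model.mean == pytest.approx(mu)
    assert model.eigenvalues == pytest.approx(vals[order])
    assert np.abs(model.eigenvectors) == pytest.approx(np.abs(vecs[:, order]))


def test_fit_recovers_multivariate_normal_mean():
    env = _env_pair(5, n=60)
    rng = np.random.default_rng(6)
    # occurrences drawn uniformly: model mean ~ mean environment of cells
    pts = np.column_stack([rng.uniform(10, 8990, 2000),
                           rng.uniform(10, 8990, 2000)])
    areas = np.repeat(list("abcd"), 500)
    occ = OccurrenceSet(pts, areas)
    model = fit_partitioned_d2(
        spatial_bootstrap(occ, cap=50, iterations=200, seed=7), env)
    x = env.extract(pts)
    assert model.mean == pytest.approx(x.mean(0), abs=0.1)


def test_degenerate_variable_named():
    env = EnvGrid({"flat": Grid(np.ones((10, 10)), 0, 0, 150.0),
                   "ok": Grid(np.random.default_rng(0).standard_normal((10, 10)),
                              0, 0, 150.0)})
    occ = _occ([(75 + 150 * i, 75 + 150 * j) for i in range(5) for j in range(5)])
    with pytest.raises(ValueError, match="flat"):
        fit_partitioned_d2(iter([occ]), env)


def test_default_partition_rule():
    assert default_partition(np.array([1.5, 1.2, 0.8, 0.5])) == [2, 3]
    # all eigenvalues >= 1: fall back to every component
    assert default_partition(np.array([1.0, 1.0])) == [0, 1]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _identity_model():
    return HabitatModel(["a", "b"], np.zeros(2), np.ones(2),
                        np.ones(2), np.eye(2), [0, 1])


def test_hsi_is_one_at_multivariate_mean():
    m = _identity_model()
    assert mahalanobis_d2(m, np.zeros(2)) == pytest.approx(0.0)
    assert hsi_from_d2(0.0, 2) == pytest.approx(1.0)


def test_identity_correlation_d2_is_standardized_euclidean():
    m = _identity_model()
    v = np.array([1.5, -2.0])
    assert mahalanobis_d2(m, v) == pytest.approx(float(v @ v))


def test_chi_square_rescaling_closed_form():
    # df = 2: HSI = exp(-D^2/2); D^2 = 5.991 -> 0.05
    assert hsi_from_d2(5.991, 2) == pytest.approx(math.exp(-5.991 / 2), rel=1e-6)
    assert hsi_from_d2(5.991, 2) == pytest.approx(0.05, abs=2e-4)


def test_hsi_monotone_decreasing_in_d2():
    d2 = np.array([0.0, 0.5, 1.0, 3.0, 10.0])
    hsi = hsi_from_d2(d2, 2)
    assert np.all(np.diff(hsi) < 0)


def test_hsi_invariant_to_affine_rescaling_of_inputs():
    env = _env_pair(8)
    rng = np.random.default_rng(9)
    pts = np.column_stack([rng.uniform(10, 5900, 80), rng.uniform(10, 5900, 80)])
    occ = _occ(pts)
    m1 = fit_partitioned_d2(iter([occ] * 3), env)
    h1 = score_hsi(m1, env, partition=[0, 1])
    scaled = EnvGrid({"a": Grid(env.layers["a"].values * 3.0 + 7.0, 0, 0, 150.0),
                      "b": env.layers["b"]})
    m2 = fit_partitioned_d2(iter([occ] * 3), scaled)
    h2 = score_hsi(m2, scaled, partition=[0, 1])
    assert h1.values == pytest.approx(h2.values, rel=1e-9)


def test_score_propagates_nodata():
    rng = np.random.default_rng(1)
    vals = rng.standard_normal((5, 5))
    vals[0, 0] = np.nan
    env = EnvGrid({"a": Grid(vals, 0, 0, 150.0),
                   "b": Grid(rng.standard_normal((5, 5)), 0, 0, 150.0)})
    occ = _occ([(75 + 150 * i, 75 + 150 * j) for i in range(1, 4)
                for j in range(1, 4)])
    model = fit_partitioned_d2(iter([occ] * 2), env)
    hsi = score_hsi(model, env, partition=[0, 1])
    assert np.isnan(hsi.values[0, 0])


# ---------------------------------------------------------------------------
# Thresholding and validation
# ---------------------------------------------------------------------------

def test_threshold_inclusive_and_nodata():
    vals = np.array([[0.6, 0.5], [0.4, np.nan]])
    out = threshold_suitability(Grid(vals, 0, 0, 150.0), 0.5)
    assert out.values[0, 0] == 1 and out.values[0, 1] == 1
    assert out.values[1, 0] == 0 and np.isnan(out.values[1, 1])
    with pytest.raises(ValueError):
        threshold_suitability(Grid(vals, 0, 0, 150.0), 1.5)


def test_validate_single_point_median():
    vals = np.full((4, 4), 0.3)
    vals[2, 1] = 0.8
    hsi = Grid(vals, 0, 0, 150.0)
    occ = OccurrenceSet(np.array([[225.0, 225.0]]), np.array(["x"]),
                        np.array(["validation"]))
    assert validate_model(hsi, occ) == {"validation": pytest.approx(0.8)}


def test_validate_all_nodata_errors():
    hsi = Grid(np.full((3, 3), np.nan), 0, 0, 150.0)
    occ = OccurrenceSet(np.array([[75.0, 75.0]]), np.array(["x"]))
    with pytest.raises(ValueError):
        validate_model(hsi, occ)


# ---------------------------------------------------------------------------
# Recovery on the synthetic landscape
# ---------------------------------------------------------------------------

def test_fitted_model_ranks_cells_concordantly_with_truth():
    """Spearman rho > 0.6 between fitted (full-partition) HSI and the
    generator's true suitability; occurrences score above background."""
    spec = SimulationSpec(master_seed=6)
    env, truth, occ = simulate_landscape(spec)
    occ = thin_occurrences(occ, env.ref)
    cal = occ.subset(occ.role == "calibration")
    model = fit_partitioned_d2(
        spatial_bootstrap(cal, cap=50, iterations=100, seed=1), env)
    hsi = score_hsi(model, env, partition=list(range(len(env.names))))
    ok = env.mask & truth.mask
    rho = spearmanr(hsi.values[ok], truth.values[ok]).statistic
    assert rho > 0.6

    rng = np.random.default_rng(2)
    land = np.argwhere(ok)
    bg = land[rng.choice(len(land), 500, replace=False)]
    occ_vals = np.array([hsi.value_at(x, y) for x, y in cal.points[:500]])
    bg_vals = hsi.values[bg[:, 0], bg[:, 1]]
    p = mannwhitneyu(occ_vals[~np.isnan(occ_vals)], bg_vals,
                     alternative="greater").pvalue
    assert p < 0.01


def test_model_json_round_trip(tmp_path):
    m = _identity_model()
    path = tmp_path / "model.json"
    m.to_json(path)
    back = HabitatModel.from_json(path)
    assert back.variables == m.variables
    assert back.eigenvectors == pytest.approx(m.eigenvectors)
    assert back.partition == m.partition
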