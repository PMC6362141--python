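"""Least-cost paths, buffers and dyad distances."""

import itertools
import math

import numpy as np
import pytest

from kinscape import (Grid, SampleMetadata, least_cost_distance, mean_center,
                      percent_suitable)
from kinscape.landscape import CostSurface, dyad_distances, friction_from_hsi


def test_mean_center_examples():
    assert mean_center([(3.0, 4.0)]) == (3.0, 4.0)
    assert mean_center([(0, 0), (2, 2)]) == (1.0, 1.0)
    pts = [(1.0, 2.0), (5.0, -1.0), (2.5, 7.0)]
    cx, cy = mean_center(pts)
    sx, sy = mean_center([(x + 10, y - 3) for x, y in pts])
    assert (sx, sy) == pytest.approx((cx + 10, cy - 3))
    with pytest.raises(ValueError):
        mean_center([])


def test_friction_is_inverse_hsi_with_floor():
    hsi = Grid(np.array([[1.0, 0.5, 0.0, np.nan]]), 0, 0, 150.0)
    fr = friction_from_hsi(hsi, floor=0.01)
    assert fr.values[0, 0] == 1.0
    assert fr.values[0, 1] == 2.0
    assert fr.values[0, 2] == 100.0
    assert np.isnan(fr.values[0, 3])
    fr2 = friction_from_hsi(hsi, impassable_zero=True)
    assert np.isnan(fr2.values[0, 2])


def test_uniform_surface_lcp_equals_lattice_euclidean():
    fr = Grid(np.ones((5, 12)), 0, 0, 150.0)
    a = (75.0, 75.0)
    b = (75.0 + 10 * 150, 75.0)
    assert least_cost_distance(fr, a, b) == pytest.approx(10 * 150)
    # diagonal lattice direction
    c = (75.0 + 3 * 150, 75.0 + 3 * 150)
    assert least_cost_distance(fr, a, c) == pytest.approx(3 * 150 * math.sqrt(2))


def _brute_force_lcp(grid_vals, start, goal, cellsize=1.0):
    """DFS over all simple paths on a small grid (independent oracle)."""
    nrows, ncols = grid_vals.shape
    best = [math.inf]

    def neighbors(cell):
        r, c = cell
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    step = cellsize * (math.sqrt(2) if dr and dc else 1.0)
                    cost = 0.5 * (grid_vals[r, c] + grid_vals[rr, cc]) * step
                    yield (rr, cc), cost

    def dfs(cell, visited, acc):
        if acc >= best[0]:
            return
        if cell == goal:
            best[0] = acc
            return
        for nxt, cost in neighbors(cell):
            if nxt not in visited:
                dfs(nxt, visited | {nxt}, acc + cost)

    dfs(start, {start}, 0.0)
    return best[0]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_dijkstra_matches_brute_force_on_3x3(seed):
    rng = np.random.default_rng(seed)
    vals = 1.0 + 9.0 * rng.random((3, 3))
    fr = Grid(vals, 0, 0, 1.0)
    surface = CostSurface(fr)
    cells = [(r, c) for r in range(3) for c in range(3)]
    for start, goal in itertools.combinations(cells, 2):
        a = (start[1] + 0.5, 3 - start[0] - 0.5)
        b = (goal[1] + 0.5, 3 - goal[0] - 0.5)
        assert surface.distance(a, b) == pytest.approx(
            _brute_force_lcp(vals, start, goal))


def test_high_cost_center_cell_is_avoided():
    vals = np.ones((3, 3))
    vals[1, 1] = 100.0
    fr = Grid(vals, 0, 0, 1.0)
    d = least_cost_distance(fr, (0.5, 1.5), (2.5, 1.5))
    assert d == pytest.approx(2 * math.sqrt(2))  # detour over the corners


def test_lcp_symmetric_and_triangle():
    rng = np.random.default_rng(5)
    fr = Grid(1.0 + rng.random((6, 6)), 0, 0, 1.0)
    s = CostSurface(fr)
    pts = [(0.5, 0.5), (5.5, 5.5), (0.5, 5.5)]
    for a, b in itertools.combinations(pts, 2):
        assert s.distance(a, b) == pytest.approx(s.distance(b, a))
    assert (s.distance(pts[0], pts[1])
            <= s.distance(pts[0], pts[2]) + s.distance(pts[2], pts[1]) + 1e-9)


def test_8_connectivity_discretization_bound():
    fr = Grid(np.ones((30, 30)), 0, 0, 1.0)
    s = CostSurface(fr)
    rng = np.random.default_rng(7)
    a = (0.5, 0.5)
    for _ in range(20):
        b = (rng.integers(1, 30) - 0.5, rng.integers(1, 30) - 0.5)
        lcp = s.distance(a, b)
        assert lcp / max(math.dist(a, b), 1e-9) <= 1.083 + 1e-6


def test_nodata_endpoint_and_unreachable():
    vals = np.ones((3, 3))
    vals[:, 1] = np.nan
    fr = Grid(vals, 0, 0, 1.0)
    s = CostSurface(fr)
    with pytest.raises(ValueError, match="nodata"):
        s.distance((1.5, 1.5), (0.5, 0.5))
    assert math.isinf(s.distance((0.5, 0.5), (2.5, 0.5)))


def test_same_cell_straight_line():
    fr = Grid(np.ones((3, 3)), 0, 0, 150.0)
    s = CostSurface(fr)
    assert s.distance((10.0, 10.0), (40.0, 50.0)) == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# Buffers
# ---------------------------------------------------------------------------

def test_percent_suitable_all_suitable():
    hsi = Grid(np.full((10, 10), 0.9), 0, 0, 150.0)
    assert percent_suitable(hsi, (750, 750), 500) == 100.0


def test_percent_suitable_matches_cell_count_oracle():
    rng = np.random.default_rng(3)
    vals = rng.random((10, 10))
    hsi = Grid(vals, 0, 0, 150.0)
    center, radius = (750.0, 750.0), 600.0
    got = percent_suitable(hsi, center, radius, threshold=0.5)
    count = suit = 0
    for r in range(10):
        for c in range(10):
            x, y = hsi.cell_center(r, c)
            if (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius ** 2:
                count += 1
                suit += vals[r, c] >= 0.5
    assert got == pytest.approx(100 * suit / count)


def test_percent_suitable_excludes_ocean_from_denominator():
    vals = np.full((10, 10), 0.9)
    vals[:, :5] = np.nan  # ocean half
    hsi = Grid(vals, 0, 0, 150.0)
    assert percent_suitable(hsi, (750, 750), 10_000) == 100.0


def test_percent_suitable_monotone_in_threshold():
    rng = np.random.default_rng(4)
    hsi = Grid(rng.random((12, 12)), 0, 0, 150.0)
    pts = [percent_suitable(hsi, (900, 900), 800, threshold=t)
           for t in (0.2, 0.4, 0.6, 0.8)]
    assert pts == sorted(pts, reverse=True)


def test_percent_suitable_all_nodata_errors():
    hsi = Grid(np.full((4, 4), np.nan), 0, 0, 150.0)
    with pytest.raises(ValueError):
        percent_suitable(hsi, (300, 300), 200)


# ---------------------------------------------------------------------------
# Dyad distances
# ---------------------------------------------------------------------------

def _meta(d):
    return {k: SampleMetadata(k, x, y, aggregation=agg)
            for k, (x, y, agg) in d.items()}


def test_dyad_distances_fill_and_flags():
    vals = np.ones((4, 4))
    vals[:, 2] = 50.0  # costly strip
    fr = Grid(vals, 0, 0, 1.0)
    meta = _meta({"a": (0.5, 0.5, "west"), "b": (3.5, 0.5, "east"),
                  "c": (0.5, 0.6, "west")})
    dyads = dyad_distances([("a", "b"), ("a", "c")], meta, fr)
    ab = dyads[0]
    assert ab.lcp_m > ab.euclid_m          # detour around the strip
    assert ab.cross_aggregation
    ac = dyads[1]
    assert ac.euclid_m == pytest.approx(0.1)
    assert not ac.cross_aggregation


def test_dyad_distances_coincident_zero():
    fr = Grid(np.ones((3, 3)), 0, 0, 1.0)
    meta = _meta({"a": (1.5, 1.5, "x"), "b": (1.5, 1.5, "x")})
    d = dyad_distances([("a", "b")], meta, fr)[0]
    assert d.euclid_m == 0.0 and d.lcp_m == 0.0


def test_dyad_distances_skips_missing_member():
    fr = Grid(np.ones((3, 3)), 0, 0, 1.0)
    meta = _meta({"a": (0.5, 0.5, "x")})
    with pytest.warns(UserWarning, match="skipped"):
        out = dyad_distances([("a", "zz")], meta, fr)
    assert out == []
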