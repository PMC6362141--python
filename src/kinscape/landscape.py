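"""Euclidean and least-cost-path landscape distances and buffer summaries.

A friction surface is the inverse of the habitat suitability index (HSI is
floored before inversion so barren cells are traversable but strongly
avoided, unless they are declared impassable).  Least-cost paths run on the
8-connected cell graph with edge cost = mean friction of the two cells
times the center-to-center distance, so on a friction-1 surface the
least-cost distance equals the lattice path length (within the 8-connectivity
discretization factor <= 1.083 of Euclidean off-lattice directions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import Grid
from .kinship import RelativeDyad

HSI_FLOOR = 0.01


def friction_from_hsi(hsi: Grid, floor: float = HSI_FLOOR,
                      impassable_zero: bool = False) -> Grid:
    """Friction = 1 / max(HSI, floor); optionally HSI = 0 becomes nodata."""
    vals = hsi.values.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 1.0 / np.clip(vals, floor, None)
    if impassable_zero:
        out[vals == 0] = np.nan
    out[np.isnan(vals)] = np.nan
    return hsi.like(out)


def mean_center(points) -> tuple[float, float]:
    """Arithmetic mean of a list of (x, y) coordinates."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("mean center of an empty point set")
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


class CostSurface:
    """Dijkstra least-cost distances over a friction raster.

    Edges connect 8-neighboring data cells; an edge's cost is the mean of
    the two cells' friction values times the center distance (cellsize, or
    cellsize * sqrt(2) diagonally).  Distances are in meter-equivalents:
    they reduce to path length where friction is 1.
    """

    _OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]

    def __init__(self, friction: Grid):
        vals = friction.values
        if np.nanmin(vals) < 1.0 - 1e-9:
            raise ValueError("friction must be >= 1 everywhere")
        self.grid = friction
        ok = friction.mask
        self.node_id = np.full(vals.shape, -1, dtype=np.int64)
        self.node_id[ok] = np.arange(ok.sum())
        self.n_nodes = int(ok.sum())
        rows_i, cols_i, weights = [], [], []
        cs = friction.cellsize
        nrows, ncols = vals.shape
        for dr, dc in self._OFFSETS:
            r0 = np.arange(max(0, -dr), min(nrows, nrows - dr))
            c0 = np.arange(max(0, -dc), min(ncols, ncols - dc))
            if len(r0) == 0 or len(c0) == 0:
                continue
            rr, cc = np.meshgrid(r0, c0, indexing="ij")
            a = self.node_id[rr, cc]
            b = self.node_id[rr + dr, cc + dc]
            fa = vals[rr, cc]
            fb = vals[rr + dr, cc + dc]
            good = (a >= 0) & (b >= 0)
            dist = cs * math.sqrt(2) if dr and dc else cs
            rows_i.append(a[good])
            cols_i.append(b[good])
            weights.append(0.5 * (fa[good] + fb[good]) * dist)
        self.graph = coo_matrix(
            (np.concatenate(weights),
             (np.concatenate(rows_i), np.concatenate(cols_i))),
            shape=(self.n_nodes, self.n_nodes)).tocsr()
        self._dist_cache: dict[int, np.ndarray] = {}

    def _node(self, point) -> int:
        r, c = self.grid.cell_of(*point)
        node = int(self.node_id[r, c])
        if node < 0:
            raise ValueError(f"point {tuple(point)} lies on a nodata cell")
        return node

    def distances_from(self, point) -> np.ndarray:
        src = self._node(point)
        if src not in self._dist_cache:
            self._dist_cache[src] = dijkstra(self.graph, indices=src,
                                             directed=False)
        return self._dist_cache[src]

    def distance(self, a, b) -> float:
        """Least-cost distance between two points (meter-equivalents).

        Points in the same cell return the straight-line within-cell
        distance.  An unreachable destination returns inf.
        """
        na, nb = self._node(a), self._node(b)
        if na == nb:
            return float(math.dist(a, b))
        return float(self.distances_from(a)[nb])


def least_cost_distance(friction: Grid, a, b) -> float:
    """One-shot least-cost distance (see :class:`CostSurface`)."""
    return CostSurface(friction).distance(a, b)


def percent_suitable(hsi: Grid, center, radius_m: float,
                     threshold: float = 0.5) -> float:
    """Percent of land cells within the buffer whose HSI >= threshold.

    Cell membership is by cell-center-in-circle; nodata (ocean) cells are
    excluded from numerator and denominator.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    xs, ys = hsi.centers()
    within = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius_m ** 2
    land = within & hsi.mask
    n_land = int(land.sum())
    if n_land == 0:
        raise ValueError("buffer contains no land cells")
    n_suit = int(np.sum(hsi.values[land] >= threshold))
    return 100.0 * n_suit / n_land


def buffer_summaries(hsi: Grid, centers: dict[str, tuple[float, float]],
                     radii_m=(5_000.0, 30_000.0), threshold: float = 0.5):
    """Percent suitable habitat per aggregation center per buffer radius."""
    import pandas as pd

    rows = []
    for label, center in centers.items():
        for radius in radii_m:
            rows.append({"aggregation": label, "radius_m": radius,
                         "pct_suitable": percent_suitable(hsi, center, radius,
                                                          threshold)})
    return pd.DataFrame(rows)


def dyad_distances(pairs, meta: dict, friction: Grid,
                   probabilities: dict | None = None) -> list[RelativeDyad]:
    """Fill Euclidean and least-cost distances and region labels for dyads.

    ``pairs`` is a list of (id1, id2); members without coordinates are
    skipped with a warning.  Euclidean distances use the true capture
    coordinates; least-cost distances the cell-center path on the friction
    surface.
    """
    import warnings

    surface = CostSurface(friction)
    out = []
    for id1, id2 in pairs:
        m1, m2 = meta.get(str(id1)), meta.get(str(id2))
        if m1 is None or m2 is None:
            warnings.warn(f"dyad ({id1}, {id2}) lacks coordinates; skipped")
            continue
        p1, p2 = (m1.x, m1.y), (m2.x, m2.y)
        prob = (probabilities or {}).get((str(id1), str(id2)), 1.0)
        out.append(RelativeDyad(
            str(id1), str(id2), float(prob),
            euclid_m=float(math.dist(p1, p2)),
            lcp_m=surface.distance(p1, p2),
            region1=m1.aggregation, region2=m2.aggregation))
    return out
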