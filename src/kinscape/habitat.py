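"""Partitioned Mahalanobis D^2 habitat suitability modelling.

The model measures how similar each raster cell's environment is to the
multivariate mean of the conditions at species occurrence points.  To avoid
biasing that mean toward densely surveyed areas, occurrences are spatially
bootstrapped (each geographic area capped per iteration) and a PCA of the
standardized environmental values is fitted to every bootstrap sample; the
PCA outputs are averaged across iterations after correcting eigenvector
sign ambiguity against the first iteration.  D^2 is then computed on a
partition of the averaged components — by default the low-variance
(eigenvalue < 1) components, which capture environmental conditions that
are consistently constrained at occupied sites — and rescaled to a habitat
suitability index (HSI) in [0, 1] via the chi-square upper-tail
transform with df equal to the partition size, so HSI = 1 at the
multivariate mean and decreases monotonically in D^2.  The chi-square
rescaling is one standard choice among several; it is isolated in
:func:`hsi_from_d2` so a min-max alternative can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .grids import EnvGrid, Grid


@dataclass
class OccurrenceSet:
    """Species occurrence points with geographic-area and role labels."""

    points: np.ndarray                      # (n, 2) planar meters
    geographic_area: np.ndarray             # (n,) labels
    role: np.ndarray | None = None          # "calibration" / "validation"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.geographic_area = np.asarray(self.geographic_area)
        if self.role is None:
            self.role = np.full(len(self.points), "calibration")
        self.role = np.asarray(self.role)
        if not (len(self.points) == len(self.geographic_area) == len(self.role)):
            raise ValueError("points, areas and roles must align")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, idx) -> "OccurrenceSet":
        return OccurrenceSet(self.points[idx], self.geographic_area[idx],
                             self.role[idx])


def thin_occurrences(occ: OccurrenceSet, grid: Grid) -> OccurrenceSet:
    """Keep at most one occurrence per grid cell (first encountered)."""
    seen: set[tuple[int, int]] = set()
    keep = []
    for i, (x, y) in enumerate(occ.points):
        cell = grid.cell_of(x, y)
        if cell not in seen:
            seen.add(cell)
            keep.append(i)
    return occ.subset(np.array(keep, dtype=int))


def spatial_bootstrap(occurrences: OccurrenceSet, cap: int = 50,
                      iterations: int = 1000, seed: int | None = 0):
    """Yield per-iteration occurrence subsets capped per geographic area.

    Each iteration samples without replacement min(cap, n_area) points from
    every geographic area, equalizing the influence of densely and sparsely
    surveyed regions on the model mean.
    """
    if len(occurrences) == 0:
        raise ValueError("empty occurrence set")
    rng = np.random.default_rng(seed)
    areas = {}
    for label in np.unique(occurrences.geographic_area):
        areas[label] = np.flatnonzero(occurrences.geographic_area == label)
    for _ in range(iterations):
        idx = []
        for label in sorted(areas):
            pool = areas[label]
            take = min(cap, len(pool))
            idx.append(rng.choice(pool, size=take, replace=False))
        yield occurrences.subset(np.sort(np.concatenate(idx)))


@dataclass
class HabitatModel:
    """Averaged-PCA habitat model: means, scales, eigenstructure, partition."""

    variables: list[str]
    mean: np.ndarray           # raw-unit multivariate mean of occurrences
    scale: np.ndarray          # raw-unit standard deviations
    eigenvalues: np.ndarray    # averaged, descending
    eigenvectors: np.ndarray   # columns, averaged and renormalized
    partition: list[int]       # component indices entering D^2
    n_iterations: int = 1
    cap: int | None = None

    def to_json(self, path=None) -> str:
        doc = {
            "variables": self.variables,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "partition": list(self.partition),
            "n_iterations": self.n_iterations,
            "cap": self.cap,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "HabitatModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(doc["variables"], np.array(doc["mean"]),
                   np.array(doc["scale"]), np.array(doc["eigenvalues"]),
                   np.array(doc["eigenvectors"]), list(doc["partition"]),
                   doc.get("n_iterations", 1), doc.get("cap"))


def default_partition(eigenvalues: np.ndarray) -> list[int]:
    """Components with averaged eigenvalue < 1 (the 'constant' axes);
    falls back to all components if none qualify."""
    idx = [int(i) for i, v in enumerate(eigenvalues) if v < 1.0]
    return idx if idx else list(range(len(eigenvalues)))


def fit_partitioned_d2(subsets, env: EnvGrid, cap: int | None = None
                       ) -> HabitatModel:
    """Fit the averaged-PCA Mahalanobis model over bootstrap subsets.

    Per iteration: environmental values at the subset's points are
    standardized, a PCA of their correlation matrix taken, eigenvectors
    sign-corrected against the first iteration, and means, scales,
    eigenvalues and eigenvectors accumulated; averages define the model.
    """
    names = env.names
    p = len(names)
    if p < 2:
        raise ValueError("need at least 2 environmental variables")
    sum_mean = np.zeros(p)
    sum_scale = np.zeros(p)
    sum_vals = np.zeros(p)
    sum_vecs = np.zeros((p, p))
    ref_vecs = None
    n_iter = 0
    for subset in subsets:
        x = env.extract(subset.points)
        x = x[~np.isnan(x).any(axis=1)]
        if len(x) < p + 1:
            raise ValueError("subset smaller than variables + 1")
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = names[int(np.argmin(sd))]
            raise ValueError(f"degenerate variable (zero variance): {bad}")
        corr = np.corrcoef((x - mu) / sd, rowvar=False)
        vals, vecs = np.linalg.eigh(corr)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        if ref_vecs is None:
            ref_vecs = vecs.copy()
        else:
            flip = np.sign(np.sum(vecs * ref_vecs, axis=0))
            flip[flip == 0] = 1.0
            vecs = vecs * flip
        sum_mean += mu
        sum_scale += sd
        sum_vals += vals
        sum_vecs += vecs
        n_iter += 1
    if n_iter == 0:
        raise ValueError("no bootstrap subsets provided")
    mean = sum_mean / n_iter
    scale = sum_scale / n_iter
    vals = np.maximum(sum_vals / n_iter, 0.0)
    vecs = sum_vecs / n_iter
    norms = np.linalg.norm(vecs, axis=0)
    norms[norms == 0] = 1.0
    vecs = vecs / norms
    return HabitatModel(list(names), mean, scale, vals, vecs,
                        default_partition(vals), n_iterations=n_iter, cap=cap)


def hsi_from_d2(d2: np.ndarray, df: int) -> np.ndarray:
    """Rescale Mahalanobis D^2 to [0, 1]: chi-square upper-tail probability."""
    return chi2.sf(d2, df)


def mahalanobis_d2(model: HabitatModel, values: np.ndarray,
                   partition: list[int] | None = None) -> np.ndarray:
    """Partitioned D^2 of raw-unit environment rows against the model."""
    part = model.partition if partition is None else list(partition)
    if not set(part) <= set(range(len(model.eigenvalues))):
        raise ValueError("partition must index fitted components")
    z = (np.asarray(values, dtype=float) - model.mean) / model.scale
    scores = z @ model.eigenvectors[:, part]
    lam = model.eigenvalues[part]
    if np.any(lam <= 0):
        raise ValueError("non-positive eigenvalue in partition")
    return np.sum(scores ** 2 / lam, axis=-1)


def score_hsi(model: HabitatModel, env: EnvGrid,
              partition: list[int] | None = None) -> Grid:
    """HSI raster in [0, 1]; nodata wherever any input layer is nodata."""
    part = model.partition if partition is None else list(partition)
    stack = env.stack()
    ok = env.mask
    flat = stack[ok]
    d2 = mahalanobis_d2(model, flat, part)
    out = np.full(ok.shape, np.nan)
    out[ok] = hsi_from_d2(d2, len(part))
    return env.ref.like(out)


def threshold_suitability(hsi: Grid, threshold: float = 0.5) -> Grid:
    """Binary suitable (1) / unsuitable (0) raster; HSI >= threshold is suitable."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    vals = np.where(hsi.values >= threshold, 1.0, 0.0)
    vals[np.isnan(hsi.values)] = np.nan
    return hsi.like(vals)


def validate_model(hsi: Grid, points: OccurrenceSet) -> dict[str, float]:
    """Median HSI at occurrence cells, per role (calibration/validation)."""
    out = {}
    for role in np.unique(points.role):
        sub = points.points[points.role == role]
        vals = np.array([hsi.value_at(x, y) for x, y in sub])
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"all {role} points fall on nodata")
        out[str(role)] = float(np.median(vals))
    return out
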