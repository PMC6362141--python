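"""Synthetic data generators for every stage of the pipeline.

The genotype generator emulates the empirical study conditions: ~270
individuals in 18 local aggregations genotyped at 19 microsatellite loci
with about 10 alleles per locus (Dirichlet(0.5) ancestral frequencies give
expected heterozygosity near 0.78), weak island-model differentiation
(Balding-Nichols deme frequencies at a target FST), a small genotyping
error rate, and optionally planted first-order relative dyads.  The
landscape generator produces smooth Gaussian-random-field environmental
layers, a known true suitability surface, occurrence points sampled from it
and an ocean (nodata) margin, so habitat-model recovery can be benchmarked
against truth.  Every output is fully determined by the spec's master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .genodata import MISSING, GenotypeTable, SampleMetadata
from .grids import EnvGrid, Grid
from .habitat import OccurrenceSet


@dataclass
class SimulationSpec:
    """Study-condition parameters for the synthetic generators."""

    n_demes: int = 18
    n_per_deme: int = 15
    n_loci: int = 19
    alleles_per_locus: int = 10
    target_fst: float = 0.02
    epsilon: float = 0.001             # genotyping error rate
    dirichlet_alpha: float = 0.5       # ancestral frequency concentration
    planted_dyads: list = field(default_factory=list)  # (category, deme1, deme2)
    raster_shape: tuple = (100, 100)
    cellsize_m: float = 150.0
    n_env: int = 4
    smooth_sigma: float = 10.0
    ocean_cols: int = 8
    n_occurrences: int = 600
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        for name in ("n_demes", "n_per_deme", "n_loci", "alleles_per_locus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def spec_hash(self) -> str:
        doc = asdict(self)
        doc["planted_dyads"] = [list(d) for d in doc["planted_dyads"]]
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _apply_error_process(calls: np.ndarray, alleles: int, epsilon: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Observed allele = true with prob 1-eps, else uniform over the others."""
    if epsilon <= 0 or alleles < 2:
        return calls
    out = calls.copy()
    flat = out.reshape(-1)
    hit = (flat != MISSING) & (rng.random(flat.shape) < epsilon)
    repl = rng.integers(0, alleles - 1, size=int(hit.sum())) + 1
    cur = flat[hit]
    flat[hit] = np.where(repl >= cur, repl + 1, repl)
    return out


def _deme_frequencies(anc: np.ndarray, fst: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols deme frequencies: Dirichlet(p_anc (1-F)/F)."""
    if fst == 0:
        return anc.copy()
    return rng.dirichlet(anc * (1.0 - fst) / fst)


def simulate_island_genotypes(spec: SimulationSpec, seed: int | None = None
                              ) -> tuple[GenotypeTable, dict]:
    """Island-model genotypes in HWE within demes.

    Returns (table, truth), where truth holds the ancestral and per-deme
    allele frequencies actually used.
    """
    rng = np.random.default_rng(spec.master_seed if seed is None else seed)
    k = spec.alleles_per_locus
    ancestral = [rng.dirichlet(np.full(k, spec.dirichlet_alpha))
                 for _ in range(spec.n_loci)]
    deme_freqs = [[_deme_frequencies(anc, spec.target_fst, rng)
                   for anc in ancestral] for _ in range(spec.n_demes)]
    n_total = spec.n_demes * spec.n_per_deme
    calls = np.empty((n_total, spec.n_loci, 2), dtype=np.int32)
    individuals, aggregations = [], []
    row = 0
    for d in range(spec.n_demes):
        for i in range(spec.n_per_deme):
            individuals.append(f"ind_{d:02d}_{i:03d}")
            aggregations.append(f"deme_{d:02d}")
            for j in range(spec.n_loci):
                calls[row, j] = rng.choice(k, size=2, p=deme_freqs[d][j]) + 1
            row += 1
    calls = _apply_error_process(calls, k, spec.epsilon, rng)
    table = GenotypeTable(individuals, [f"loc_{j:02d}" for j in range(spec.n_loci)],
                          calls, aggregations)
    return table, {"ancestral": ancestral, "deme_freqs": deme_freqs}


def plant_relatives(table: GenotypeTable, spec: SimulationSpec,
                    truth: dict, seed: int | None = None
                    ) -> tuple[GenotypeTable, list[dict]]:
    """Overwrite pairs of individuals with Mendelian first-order relatives.

    For each (category, deme1, deme2) in ``spec.planted_dyads``, parents are
    drawn from deme1's frequencies and the two members generated by
    Mendelian transmission; the second member is placed in deme2 (equal to
    deme1 for within-deme dyads).  Existing individuals of those demes are
    overwritten, consuming them in order, so the table size is unchanged.
    Returns the new table and the dyad truth records.
    """
    rng = np.random.default_rng(
        (spec.master_seed + 1) if seed is None else seed)
    calls = table.calls.copy()
    members = table.group_members()
    cursor = {label: 0 for label in members}
    k = spec.alleles_per_locus
    records = []

    def next_slot(deme: str) -> int:
        idx = cursor[deme]
        if idx >= len(members[deme]):
            raise ValueError(f"deme {deme} exhausted while planting dyads")
        cursor[deme] += 1
        return table.index_of(members[deme][idx])

    for category, deme1, deme2 in spec.planted_dyads:
        freqs = truth["deme_freqs"][int(deme1.split("_")[1])]
        g1 = np.empty((table.n_loci, 2), dtype=np.int32)
        g2 = np.empty((table.n_loci, 2), dtype=np.int32)
        for j in range(table.n_loci):
            p = freqs[j]
            father = rng.choice(k, size=2, p=p)
            mother = rng.choice(k, size=2, p=p)
            if category == "PO":
                child = (father[rng.integers(2)], rng.choice(k, p=p))
                a, b = father, np.array(child)
            elif category == "FS":
                a = np.array([father[rng.integers(2)], mother[rng.integers(2)]])
                b = np.array([father[rng.integers(2)], mother[rng.integers(2)]])
            elif category == "HS":
                mother2 = rng.choice(k, size=2, p=p)
                a = np.array([father[rng.integers(2)], mother[rng.integers(2)]])
                b = np.array([father[rng.integers(2)], mother2[rng.integers(2)]])
            else:
                raise ValueError(f"unknown dyad category {category}")
            g1[j] = a + 1
            g2[j] = b + 1
        i1 = next_slot(deme1)
        i2 = next_slot(deme2)
        calls[i1] = _apply_error_process(g1[None], k, spec.epsilon, rng)[0]
        calls[i2] = _apply_error_process(g2[None], k, spec.epsilon, rng)[0]
        records.append({"category": category,
                        "id1": table.individuals[i1], "deme1": deme1,
                        "id2": table.individuals[i2], "deme2": deme2})
    out = GenotypeTable(list(table.individuals), list(table.loci), calls,
                        list(table.aggregations) if table.aggregations else None)
    return out, records


def simulate_landscape(spec: SimulationSpec, seed: int | None = None
                       ) -> tuple[EnvGrid, Grid, OccurrenceSet]:
    """Synthetic environmental stack, true-suitability raster and occurrences.

    Environmental layers are smoothed Gaussian random fields; true
    suitability decreases in the Mahalanobis distance of a cell's
    environment from a chosen optimum; occurrences are sampled across six
    vertical geographic areas with probability proportional to true
    suitability; the left margin is ocean (nodata).
    """
    rng = np.random.default_rng(
        (spec.master_seed + 2) if seed is None else seed)
    nrows, ncols = spec.raster_shape
    cs = spec.cellsize_m
    layers = {}
    fields = []
    for v in range(spec.n_env):
        f = gaussian_filter(rng.standard_normal((nrows, ncols)),
                            spec.smooth_sigma, mode="reflect")
        f = (f - f.mean()) / f.std()
        fields.append(f)
        vals = f.copy()
        vals[:, :spec.ocean_cols] = np.nan
        layers[f"env_{v}"] = Grid(vals, 0.0, 0.0, cs)
    env = EnvGrid(layers)
    stack = np.stack(fields, axis=-1)
    # optimum: environment at the most "central" land cell of field space
    opt = np.array([np.quantile(f[:, spec.ocean_cols:], 0.7) for f in fields])
    d2 = np.sum((stack - opt) ** 2, axis=-1)
    truth_vals = np.exp(-d2 / 2.0)
    truth_vals[:, :spec.ocean_cols] = np.nan
    truth = Grid(truth_vals, 0.0, 0.0, cs)

    land = ~np.isnan(truth_vals)
    weights = np.where(land, np.nan_to_num(truth_vals), 0.0).reshape(-1)
    weights = weights / weights.sum()
    cells = rng.choice(nrows * ncols, size=spec.n_occurrences, replace=True,
                       p=weights)
    rows, cols = np.divmod(cells, ncols)
    jitter = rng.uniform(-0.4, 0.4, size=(spec.n_occurrences, 2)) * cs
    xs = (cols + 0.5) * cs + jitter[:, 0]
    ys = (nrows - rows - 0.5) * cs + jitter[:, 1]
    # six vertical geographic areas over the land portion
    land_w = ncols - spec.ocean_cols
    area = np.clip(((cols - spec.ocean_cols) * 6) // max(land_w, 1), 0, 5)
    roles = np.where(rng.random(spec.n_occurrences) < 0.5,
                     "calibration", "validation")
    occ = OccurrenceSet(np.column_stack([xs, ys]),
                        np.array([f"area_{a}" for a in area]), roles)
    return env, truth, occ


def simulate_wright_fisher(ne: int, s_sample: int, n_loci: int = 20,
                           n_alleles: int = 10, generations: int = 50,
                           seed: int | None = 0) -> GenotypeTable:
    """Diploid Wright-Fisher population; returns a sample of S individuals.

    Random mating with free recombination between loci; initial allele
    frequencies equifrequent.  Linkage disequilibrium among unlinked loci
    equilibrates within a few generations and carries the 1/(3Ne) drift
    signal that the LD method inverts.
    """
    rng = np.random.default_rng(seed)
    # population genotypes: (ne, n_loci, 2)
    pop = rng.integers(0, n_alleles, size=(ne, n_loci, 2)).astype(np.int32)
    for _ in range(generations):
        mothers = rng.integers(0, ne, size=ne)
        fathers = rng.integers(0, ne, size=ne)
        m_gam = pop[mothers[:, None], np.arange(n_loci)[None, :],
                    rng.integers(0, 2, size=(ne, n_loci))]
        f_gam = pop[fathers[:, None], np.arange(n_loci)[None, :],
                    rng.integers(0, 2, size=(ne, n_loci))]
        pop = np.stack([m_gam, f_gam], axis=-1)
    take = rng.choice(ne, size=min(s_sample, ne), replace=False)
    calls = pop[take] + 1
    inds = [f"wf_{i:04d}" for i in range(len(take))]
    return GenotypeTable(inds, [f"loc_{j:02d}" for j in range(n_loci)], calls)


def synthetic_metadata(table: GenotypeTable, spec: SimulationSpec,
                       seed: int | None = None) -> dict[str, SampleMetadata]:
    """Capture coordinates: deme centers gridded over the land portion of the
    synthetic raster extent, individuals jittered around them."""
    rng = np.random.default_rng(
        (spec.master_seed + 3) if seed is None else seed)
    demes = sorted(set(table.aggregations or []))
    nrows, ncols = spec.raster_shape
    cs = spec.cellsize_m
    x0 = (spec.ocean_cols + 2) * cs
    x1 = (ncols - 2) * cs
    y0, y1 = 2 * cs, (nrows - 2) * cs
    side = int(np.ceil(np.sqrt(max(len(demes), 1))))
    jitter_sd = min(x1 - x0, y1 - y0) / (side * 8)
    centers = {}
    for i, d in enumerate(demes):
        fx = (i % side + 0.5) / side
        fy = (i // side + 0.5) / side
        centers[d] = (x0 + fx * (x1 - x0), y0 + fy * (y1 - y0))
    out = {}
    for ind, agg in zip(table.individuals, table.aggregations or []):
        cx, cy = centers[agg]
        out[ind] = SampleMetadata(
            ind,
            float(np.clip(cx + rng.normal(0, jitter_sd), x0, x1)),
            float(np.clip(cy + rng.normal(0, jitter_sd), y0, y1)),
            sex=("M" if rng.random() < 0.5 else "F"), aggregation=agg)
    return out


def write_fixture_bundle(spec: SimulationSpec, out_dir) -> dict:
    """Emit a complete fixture directory: GENEPOP + metadata + truth + rasters.

    A manifest (master seed + spec hash) accompanies the bundle so any
    fixture is reproducible from its spec alone.
    """
    from . import genodata
    from .grids import write_ascii

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_island_genotypes(spec)
    table, dyads = plant_relatives(table, spec, truth)
    meta = synthetic_metadata(table, spec)
    genodata.write_genepop(table, out / "genotypes.gen")
    genodata.write_genotype_csv(table, out / "genotypes.csv")
    genodata.write_metadata_csv(meta, out / "metadata.csv")
    import pandas as pd

    pd.DataFrame(dyads).to_csv(out / "true_dyads.csv", index=False)
    env, truth_hsi, occ = simulate_landscape(spec)
    for name, grid in env.layers.items():
        write_ascii(grid, out / f"{name}.asc")
    write_ascii(truth_hsi, out / "true_suitability.asc")
    pd.DataFrame({"x": occ.points[:, 0], "y": occ.points[:, 1],
                  "area": occ.geographic_area, "role": occ.role}
                 ).to_csv(out / "occurrences.csv", index=False)
    manifest = {"master_seed": spec.master_seed, "spec_hash": spec.spec_hash(),
                "spec": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(spec).items()}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
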