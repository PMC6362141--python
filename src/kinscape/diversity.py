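"""Genetic diversity indices, relatedness, pairwise FST and isolation by distance.

Per-aggregation summaries (observed/expected heterozygosity, fixation index,
rarefied allelic richness, mean pairwise Queller-Goodnight relatedness),
Weir-Cockerham theta between aggregations, and the Mantel matrix-correlation
test of isolation by distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genodata import MISSING, GenotypeTable, PValue


@dataclass
class PairwiseMatrix:
    """Symmetric labelled matrix (FST or geographic distance), zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass
class DiversitySummary:
    aggregation: str
    n: int
    ho: float
    he: float
    he_unbiased: float
    f: float
    r_mean: float | None = None
    ar: float | None = None
    pct_suitable_30km: float | None = None
    pct_suitable_5km: float | None = None


def het_and_f(table: GenotypeTable, group: list[str] | None = None
              ) -> tuple[float, float, float, float]:
    """Observed and expected heterozygosity and fixation index for one group.

    Per locus: Ho = fraction of heterozygotes, He = 1 - sum(p^2) (the biased,
    GenAlEx-default estimator), unbiased He = (2n/(2n-1)) He.  F = 1 - Ho/He
    per locus, averaged over loci with He > 0.  Returned values are means
    over loci.
    """
    hos, hes, uhes, fs = [], [], [], []
    for locus in table.loci:
        counts = table.genotype_counts(locus, group)
        n = sum(counts.values())
        if n < 2:
            continue
        het = sum(c for (a, b), c in counts.items() if a != b)
        ho = het / n
        freqs = np.array(list(table.allele_frequencies(locus, group).values()))
        he = 1.0 - float(np.sum(freqs ** 2))
        hos.append(ho)
        hes.append(he)
        uhes.append(2 * n / (2 * n - 1) * he)
        if he > 0:
            fs.append(1.0 - ho / he)
    if not hos:
        raise ValueError("no scorable loci in group")
    if not fs:
        raise ValueError("all loci monomorphic: F undefined")
    return (float(np.mean(hos)), float(np.mean(hes)),
            float(np.mean(uhes)), float(np.mean(fs)))


def rarefied_allelic_richness(counts: dict[int, int] | list[int], g: int) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    Ar = sum_i [1 - C(N - N_i, g) / C(N, g)] over alleles i, where N is the
    total gene count and N_i the count of allele i (hypergeometric rarefaction).
    """
    ni = list(counts.values()) if isinstance(counts, dict) else list(counts)
    ni = [int(c) for c in ni if c > 0]
    n_total = sum(ni)
    if g < 1 or g > n_total:
        raise ValueError(f"rarefaction size g={g} must be in [1, {n_total}]")
    denom = math.comb(n_total, g)
    return float(sum(1.0 - math.comb(n_total - c, g) / denom for c in ni))


def allelic_richness(table: GenotypeTable, group: list[str], g: int | None = None,
                     groups_for_g: list[list[str]] | None = None) -> float:
    """Mean rarefied allelic richness over loci for one group.

    ``g`` defaults to the smallest per-locus gene count among the compared
    groups (``groups_for_g``), mirroring rarefaction to the least-sampled
    group.
    """
    ars = []
    for locus in table.loci:
        counts = table.allele_counts(locus, group)
        n = sum(counts.values())
        if n == 0:
            continue
        if g is None:
            pool = groups_for_g if groups_for_g is not None else [group]
            gl = min(sum(table.allele_counts(locus, grp).values()) for grp in pool)
        else:
            gl = g
        gl = min(gl, n)
        if gl < 1:
            continue
        ars.append(rarefied_allelic_richness(counts, gl))
    if not ars:
        raise ValueError("no scorable loci")
    return float(np.mean(ars))


def queller_goodnight_r(table: GenotypeTable, pair: tuple[str, str],
                        freqs: dict[str, dict[int, float]]) -> float:
    """Symmetric Queller-Goodnight relatedness for one pair of individuals.

    Numerators and denominators are summed over loci before division
    (multilocus weighting); the estimator is symmetrized by averaging the
    two reference orientations.
    """
    i1, i2 = table.index_of(pair[0]), table.index_of(pair[1])
    num_xy = den_xy = num_yx = den_yx = 0.0
    shared = 0
    for j, locus in enumerate(table.loci):
        g1 = table.calls[i1, j]
        g2 = table.calls[i2, j]
        if g1[0] == MISSING or g2[0] == MISSING:
            continue
        p = freqs[locus]
        a, b = int(g1[0]), int(g1[1])
        c, d = int(g2[0]), int(g2[1])
        shared += 1

        def terms(a, b, c, d):
            sim = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
            num = sim - p[a] - p[b]
            den = 1.0 + (a == b) - p[a] - p[b]
            return num, den

        n1, d1 = terms(a, b, c, d)
        n2, d2 = terms(c, d, a, b)
        num_xy += n1
        den_xy += d1
        num_yx += n2
        den_yx += d2
    if shared == 0:
        raise ValueError("pair shares no genotyped loci")
    return 0.5 * (num_xy / den_xy + num_yx / den_yx)


def mean_relatedness(table: GenotypeTable, group: list[str],
                     freqs: dict[str, dict[int, float]]) -> float:
    """Mean pairwise Queller-Goodnight relatedness within a group."""
    vals = []
    for idx, a in enumerate(group):
        for b in group[idx + 1:]:
            vals.append(queller_goodnight_r(table, (a, b), freqs))
    if not vals:
        raise ValueError("group needs at least two individuals")
    return float(np.mean(vals))


def pairwise_fst(table: GenotypeTable, groups: dict[str, list[str]],
                 min_size: int = 2, floor_zero: bool = False) -> PairwiseMatrix:
    """Weir-Cockerham theta between all pairs of groups.

    Negative estimates are reported as estimated unless ``floor_zero``.
    Groups below ``min_size`` individuals are excluded with a warning.
    """
    import warnings

    labels = []
    for label, members in groups.items():
        if len(members) < min_size:
            warnings.warn(f"group {label} below minimum size, excluded")
        else:
            labels.append(label)
    k = len(labels)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            theta = weir_cockerham_theta(table, [groups[labels[i]], groups[labels[j]]])
            if floor_zero:
                theta = max(theta, 0.0)
            out[i, j] = out[j, i] = theta
    return PairwiseMatrix(labels, out)


def weir_cockerham_theta(table: GenotypeTable, groups: list[list[str]]) -> float:
    """Multi-locus, multi-allele Weir-Cockerham theta across >= 2 groups."""
    r = len(groups)
    if r < 2:
        raise ValueError("need at least two groups")
    sum_a = sum_abc = 0.0
    for locus in table.loci:
        per_group = []
        for members in groups:
            counts = table.genotype_counts(locus, members)
            n = sum(counts.values())
            if n >= 1:
                per_group.append((n, counts))
        if len(per_group) < 2:
            continue
        ns = np.array([n for n, _ in per_group], dtype=float)
        ri = len(per_group)
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (ns.sum() - (ns ** 2).sum() / ns.sum()) / (ri - 1)
        if nc <= 0:
            continue
        alleles = sorted({a for _, c in per_group for g in c for a in g})
        for allele in alleles:
            p_i = np.empty(ri)
            h_i = np.empty(ri)
            for gidx, (n, counts) in enumerate(per_group):
                copies = sum(c * ((g[0] == allele) + (g[1] == allele))
                             for g, c in counts.items())
                hets = sum(c for g, c in counts.items()
                           if (allele in g) and g[0] != g[1])
                p_i[gidx] = copies / (2 * n)
                h_i[gidx] = hets / n
            pbar = float(np.sum(ns * p_i) / ns.sum())
            hbar = float(np.sum(ns * h_i) / ns.sum())
            s2 = float(np.sum(ns * (p_i - pbar) ** 2) / ((ri - 1) * nbar))
            inner = pbar * (1 - pbar) - (ri - 1) / ri * s2
            a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    if sum_abc == 0:
        raise ValueError("theta undefined: no polymorphic loci")
    return sum_a / sum_abc


def linearized_fst(matrix: PairwiseMatrix) -> PairwiseMatrix:
    """FST / (1 - FST), the standard linearization for isolation by distance."""
    vals = matrix.values / (1.0 - matrix.values)
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(list(matrix.labels), vals)


def mantel_ibd(genetic: PairwiseMatrix, geographic: PairwiseMatrix,
               permutations: int = 1000, seed: int | None = None
               ) -> tuple[float, float, PValue]:
    """Mantel matrix correlation between genetic and geographic distances.

    Returns (Z, r, one-sided p).  Z is the sum of cross-products of the
    upper-triangular elements; r the Pearson correlation of the same
    elements; p from joint row/column permutations of one matrix with the
    add-one convention (#(r_perm >= r_obs) + 1) / (permutations + 1).
    """
    if genetic.labels != geographic.labels:
        raise ValueError("matrices must share labels in the same order")
    x = genetic.values
    y = geographic.values
    iu = np.triu_indices(x.shape[0], k=1)
    xv, yv = x[iu], y[iu]
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")
    z = float(np.sum(xv * yv))
    r_obs = float(np.corrcoef(xv, yv)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    n = x.shape[0]
    for _ in range(permutations):
        perm = rng.permutation(n)
        xp = x[np.ix_(perm, perm)][iu]
        r_p = float(np.corrcoef(xp, yv)[0, 1])
        if r_p >= r_obs - 1e-12:
            hits += 1
    p = PValue((hits + 1) / (permutations + 1), method="permutation")
    return z, r_obs, p


def diversity_summary(table: GenotypeTable, groups: dict[str, list[str]],
                      freqs: dict[str, dict[int, float]] | None = None,
                      rarefaction_g: int | None = None) -> list[DiversitySummary]:
    """Per-aggregation Ho/He/F/r/Ar table (habitat columns filled elsewhere).

    Relatedness reference frequencies default to the pooled whole-dataset
    frequencies (with a small floor for unseen alleles).
    """
    if freqs is None:
        freqs = {l: table.allele_frequencies(l, floor=1e-4) for l in table.loci}
    group_lists = list(groups.values())
    out = []
    for label, members in groups.items():
        ho, he, uhe, f = het_and_f(table, members)
        r_mean = mean_relatedness(table, members, freqs) if len(members) > 1 else None
        ar = allelic_richness(table, members, g=rarefaction_g,
                              groups_for_g=group_lists)
        out.append(DiversitySummary(label, len(members), ho, he, uhe, f,
                                    r_mean=r_mean, ar=ar))
    return out
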