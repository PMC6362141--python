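"""Genic exact tests and exact-test population delimitation.

Allele-frequency homogeneity between two groups is assessed with the
probability-method exact test on the 2 x k allele-count contingency table
(multivariate hypergeometric null): the p-value is the total probability of
tables, with the observed margins, whose probability does not exceed the
observed table's.  Per-locus p-values are combined across loci with Fisher's
method after flooring, and aggregations are merged agglomeratively while the
least-differentiated pair is non-significant, which delimits populations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .genodata import MISSING, GenotypeTable, PValue


@dataclass
class AggregationSet:
    """Labelled groups of individuals with optional mean-center points."""

    labels: list[str]
    members: dict[str, list[str]]
    centers: dict[str, tuple[float, float]] = field(default_factory=dict)
    max_span_m: float = 30_000.0
    min_size: int = 5

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label in self.labels:
            mem = self.members[label]
            if seen & set(mem):
                raise ValueError("aggregation membership must be disjoint")
            seen.update(mem)

    @classmethod
    def from_metadata(cls, meta: dict, min_size: int = 5) -> "AggregationSet":
        members: dict[str, list[str]] = {}
        for m in meta.values():
            if m.aggregation is not None:
                members.setdefault(m.aggregation, []).append(m.id)
        members = {k: v for k, v in members.items() if len(v) >= min_size}
        centers = {}
        for label, mem in members.items():
            xs = [meta[i].x for i in mem]
            ys = [meta[i].y for i in mem]
            centers[label] = (float(np.mean(xs)), float(np.mean(ys)))
        return cls(sorted(members), members, centers, min_size=min_size)


@dataclass
class ExactTestResult:
    pair: tuple[str, str]
    per_locus_p: list[float]
    combined_chi2: float
    df: int
    combined_p: float


def _table_logp(x: np.ndarray, col_sums: np.ndarray, row1: int, n: int) -> float:
    # P(x) = prod_j C(C_j, x_j) / C(N, R1)
    return float(np.sum(gammaln(col_sums + 1) - gammaln(x + 1)
                        - gammaln(col_sums - x + 1))
                 - (gammaln(n + 1) - gammaln(row1 + 1) - gammaln(n - row1 + 1)))


def genic_exact_test(counts: np.ndarray, method: str = "auto",
                     mc_params: tuple[int, int, int] = (10_000, 100, 5_000),
                     seed: int | None = None,
                     enumeration_cap: int = 100_000) -> PValue:
    """Probability-method exact test on a 2 x k allele-count table.

    ``counts[g, a]`` is the gene-copy count of allele ``a`` in group ``g``.
    Enumeration sums the probabilities of all tables with the observed
    margins that are no more probable than the observed table.  When the
    table space exceeds ``enumeration_cap``, tables are sampled iid from the
    multivariate hypergeometric null (seeded); the Monte Carlo p-value uses
    the add-one estimator and reports a batch-means standard error.
    ``mc_params`` is ``(dememorization, batches, iterations)``; the
    dememorization slot is accepted for interface compatibility but unused
    by the iid sampler.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("counts must be a 2 x k table")
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("both groups must have at least one counted gene")
    if counts.shape[1] < 2:
        return PValue(1.0, method="degenerate")
    col_sums = counts.sum(axis=0)
    n = int(counts.sum())
    r1 = int(row_sums[0])
    logp_obs = _table_logp(counts[0], col_sums, r1, n)
    tol = 1e-9

    space = float(np.prod([min(c, r1) + 1.0 for c in col_sums]))
    if method == "enumeration" or (method == "auto" and space <= enumeration_cap):
        k = counts.shape[1]
        suffix = np.concatenate([np.cumsum(col_sums[::-1])[::-1][1:], [0]])
        rows: list[list[int]] = []

        def rec(j: int, rem: int, acc: list[int]):
            if j == k - 1:
                if 0 <= rem <= col_sums[j]:
                    rows.append(acc + [rem])
                return
            lo = max(0, rem - int(suffix[j]))
            hi = min(int(col_sums[j]), rem)
            for x in range(lo, hi + 1):
                rec(j + 1, rem - x, acc + [x])

        rec(0, r1, [])
        xs = np.array(rows, dtype=np.int64)
        base = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
        lps = (np.sum(gammaln(col_sums + 1) - gammaln(xs + 1)
                      - gammaln(col_sums - xs + 1), axis=1) - base)
        total = float(np.exp(lps[lps <= logp_obs + tol]).sum())
        return PValue(min(total, 1.0), method="enumeration")

    if seed is None:
        raise ValueError("seed is required for the Monte Carlo exact test")
    _, batches, iters = mc_params
    rng = np.random.default_rng(seed)
    total_iters = batches * iters
    draws = rng.multivariate_hypergeometric(col_sums, r1, size=total_iters,
                                            method="count")
    lut = gammaln(np.arange(n + 2))  # log-factorial lookup for small counts
    base = lut[n + 1] - lut[r1 + 1] - lut[n - r1 + 1]
    lps = (float(lut[col_sums + 1].sum())
           - lut[draws + 1].sum(axis=1)
           - lut[col_sums - draws + 1].sum(axis=1) - base)
    hit = (lps <= logp_obs + tol)
    batch_means = hit.reshape(batches, iters).mean(axis=1)
    p = (int(hit.sum()) + 1) / (total_iters + 1)
    se = float(np.std(batch_means, ddof=1) / math.sqrt(batches))
    return PValue(p, method="mc", se=se)


def fisher_combine(per_locus_p: list[float], floor: float = 0.0001
                   ) -> tuple[float, int, float]:
    """Fisher's method across loci with a per-locus p floor.

    Returns (chi2 statistic, degrees of freedom, combined p).  Each p is
    floored at ``floor`` so a single extreme locus cannot dominate the
    combined test.
    """
    if not per_locus_p:
        raise ValueError("no per-locus p-values to combine")
    floored = [max(float(p), floor) for p in per_locus_p]
    if any(p <= 0 or p > 1 for p in floored):
        raise ValueError("p-values must be in (0, 1]")
    stat = -2.0 * sum(math.log(p) for p in floored)
    df = 2 * len(floored)
    return stat, df, float(chi2.sf(stat, df))


def combined_exact_test(table: GenotypeTable, members1: list[str],
                        members2: list[str], pair: tuple[str, str] = ("A", "B"),
                        floor: float = 0.0001, seed: int | None = None,
                        mc_params: tuple[int, int, int] = (0, 10, 200),
                        enumeration_cap: int = 5_000) -> ExactTestResult:
    """Per-locus genic exact tests for two groups, combined with Fisher."""
    per_locus = []
    counter = 0
    for locus in table.loci:
        c1 = table.allele_counts(locus, members1)
        c2 = table.allele_counts(locus, members2)
        alleles = sorted(set(c1) | set(c2))
        if not alleles or sum(c1.values()) == 0 or sum(c2.values()) == 0:
            continue
        tab = np.array([[c1.get(a, 0) for a in alleles],
                        [c2.get(a, 0) for a in alleles]])
        sub_seed = None if seed is None else (seed * 1_000 + counter) % (2 ** 31)
        counter += 1
        per_locus.append(float(genic_exact_test(
            tab, seed=sub_seed, mc_params=mc_params,
            enumeration_cap=enumeration_cap)))
    stat, df, p = fisher_combine(per_locus, floor=floor)
    return ExactTestResult(pair, per_locus, stat, df, p)


@dataclass
class MergeStep:
    merged: tuple[str, str]
    p: float
    new_label: str


def merge_aggregations(table: GenotypeTable, groups: AggregationSet | dict,
                       alpha: float = 0.01, seed: int | None = 0,
                       floor: float = 0.0001,
                       mc_params: tuple[int, int, int] = (0, 10, 200),
                       mode: str = "components",
                       ) -> tuple[dict[str, list[str]], list[MergeStep]]:
    """Exact-test population delimitation.

    The default ``mode='components'`` runs one pass of all pairwise combined
    tests and groups aggregations into the connected components of the
    non-significant-pair graph (pairs with combined p > ``alpha`` are
    connected) — the grouping reading of "if no difference is found,
    populations are grouped", and the calibrated one: under panmixia it
    returns a single population unless the graph disconnects.

    ``mode='pooled'`` is the agglomerative alternative: while the
    least-differentiated pair of units has combined p > ``alpha``, merge it
    (pooling genotypes) and recompute tests involving the merged unit, with
    ties broken by the smaller pooled sample, then lexicographically.  Note
    that pooling after similarity-selected merges biases pooled frequencies
    apart, so this mode is anti-conservative with many null groups (it
    tends to stop above one population); it is provided for comparison, not
    as the default.

    Returns (partition mapping population label -> member aggregation labels,
    ordered merge log; empty log in components mode).
    """
    members = dict(groups.members) if isinstance(groups, AggregationSet) else {
        k: list(v) for k, v in groups.items()}
    units: dict[str, list[str]] = {k: [k] for k in members}  # unit -> aggregations
    pool: dict[str, list[str]] = {k: list(v) for k, v in members.items()}
    if len(units) < 2:
        return dict(units), []

    cache: dict[frozenset, float] = {}
    counter = [0]

    def pair_p(u1: str, u2: str) -> float:
        key = frozenset((u1, u2))
        if key not in cache:
            sub_seed = None if seed is None else (seed * 7919 + counter[0]) % (2 ** 31)
            counter[0] += 1
            res = combined_exact_test(table, pool[u1], pool[u2], (u1, u2),
                                      floor=floor, seed=sub_seed,
                                      mc_params=mc_params)
            cache[key] = res.combined_p
        return cache[key]

    if mode == "components":
        labels = sorted(units)
        parent = {l: l for l in labels}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u1, u2 in itertools.combinations(labels, 2):
            if pair_p(u1, u2) > alpha:
                parent[find(u1)] = find(u2)
        comp: dict[str, list[str]] = {}
        for l in labels:
            comp.setdefault(find(l), []).append(l)
        return {"+".join(sorted(v)): sorted(v) for v in comp.values()}, []

    log: list[MergeStep] = []
    while len(units) > 1:
        best = None
        for u1, u2 in itertools.combinations(sorted(units), 2):
            p = pair_p(u1, u2)
            pooled_n = len(pool[u1]) + len(pool[u2])
            key = (-p, pooled_n, tuple(sorted((u1, u2))))
            if best is None or key < best[0]:
                best = (key, (u1, u2), p)
        (_, (u1, u2), p) = best
        if p <= alpha:
            break
        new_label = "+".join(sorted(set(u1.split("+")) | set(u2.split("+"))))
        units[new_label] = sorted(units.pop(u1) + units.pop(u2))
        pool[new_label] = pool.pop(u1) + pool.pop(u2)
        cache = {k: v for k, v in cache.items() if not (k & {u1, u2})}
        log.append(MergeStep((u1, u2), p, new_label))
    return dict(units), log


def drop_one_per_dyad(table: GenotypeTable, dyads: list[tuple[str, str]]
                      ) -> GenotypeTable:
    """Remove one member of each supported relative dyad.

    The member with more missing data is dropped; ties break
    lexicographically.  Used for the relatives-excluded rerun of the
    delimitation analysis.
    """
    drop: set[str] = set()
    for id1, id2 in dyads:
        if id1 in drop or id2 in drop:
            continue
        m1 = int(np.sum(table.calls[table.index_of(id1), :, 0] == MISSING))
        m2 = int(np.sum(table.calls[table.index_of(id2), :, 0] == MISSING))
        if m1 > m2:
            drop.add(id1)
        elif m2 > m1:
            drop.add(id2)
        else:
            drop.add(max(id1, id2))
    keep = [i for i in table.individuals if i not in drop]
    return table.subset_individuals(keep)
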