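"""Pairwise kinship classification and dispersal-dyad summaries.

Pairs of multilocus genotypes are classified among four relationship
categories by their IBD-coefficient likelihoods:

    U  (unrelated)         k = (1, 0, 0)
    PO (parent-offspring)  k = (0, 1, 0)
    FS (full siblings)     k = (1/4, 1/2, 1/4)
    HS (half siblings)     k = (1/2, 1/2, 0)

where k = (k0, k1, k2) are the probabilities of sharing 0/1/2 alleles
identical by descent.  Per locus, L = k0 P0 + k1 P1 + k2 P2 with the P_m the
joint genotype probabilities given m IBD alleles under HWE; loci multiply.
Genotyping error is integrated analytically: each observed allele is the
true allele with probability 1 - eps, otherwise uniform over the locus's
other alleles.  "First-order" pools PO and FS, which are often
indistinguishable pairwise; a supported dyad must exceed the posterior
threshold and survive a greedy, seeded sibship-refinement pass in every
replicate.  This pairwise scheme deliberately replaces a full-pedigree
sibship reconstruction and is documented as an approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeTable

CATEGORIES = ("PO", "FS", "HS", "U")
_KCOEF = {"U": (1.0, 0.0, 0.0), "PO": (0.0, 1.0, 0.0),
          "FS": (0.25, 0.5, 0.25), "HS": (0.5, 0.5, 0.0)}
FREQ_FLOOR = 1e-4


@dataclass
class RelationshipCall:
    pair: tuple[str, str]
    category: str
    posteriors: dict[str, float]
    logliks: dict[str, float]
    first_order_posterior: float
    supported: bool = False
    duplicate: bool = False


@dataclass
class RelativeDyad:
    """A supported first-order pair with its geography (one Table-style row)."""

    id1: str
    id2: str
    probability: float
    euclid_m: float | None = None
    lcp_m: float | None = None
    region1: str | None = None
    region2: str | None = None

    @property
    def cross_aggregation(self) -> bool:
        return (self.region1 is not None and self.region2 is not None
                and self.region1 != self.region2)


@dataclass
class ConfusionSummary:
    proportions: pd.DataFrame  # rows: true category, cols: inferred; rows sum to 1
    counts: pd.DataFrame
    replicates: int
    seeds: list[int]


# ---------------------------------------------------------------------------
# Per-locus likelihood machinery
# ---------------------------------------------------------------------------

class LocusModel:
    """Precomputed joint observed-genotype probabilities for one locus.

    ``m_cat[c][i, j]`` is P(observed genotypes i, j | category c) including
    the genotyping-error model, for unordered genotype indices i, j.
    """

    def __init__(self, freqs: dict[int, float], epsilon: float):
        if not 0 <= epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if any(p <= 0 for p in freqs.values()):
            raise ValueError("allele frequencies must be positive "
                             "(apply a floor for unseen alleles)")
        self.alleles = sorted(freqs)
        p = np.array([freqs[a] for a in self.alleles], dtype=float)
        p = p / p.sum()
        self.p = p
        k = len(p)
        self.genotypes = [(i, j) for i in range(k) for j in range(i, k)]
        gindex = {g: t for t, g in enumerate(self.genotypes)}
        self.gindex = gindex
        m = len(self.genotypes)

        hwe = np.array([p[i] * p[j] * (2 if i != j else 1)
                        for (i, j) in self.genotypes])
        self.hwe = hwe
        j0 = np.outer(hwe, hwe)
        j2 = np.diag(hwe)
        j1 = np.zeros((m, m))
        for x in range(k):          # shared IBD allele
            for u in range(k):      # non-IBD allele of individual 1
                for v in range(k):  # non-IBD allele of individual 2
                    g1 = gindex[(min(x, u), max(x, u))]
                    g2 = gindex[(min(x, v), max(x, v))]
                    j1[g1, g2] += p[x] * p[u] * p[v]

        if epsilon > 0 and k > 1:
            e1 = np.full((k, k), epsilon / (k - 1))
            np.fill_diagonal(e1, 1.0 - epsilon)
            e = np.zeros((m, m))  # e[obs, true]
            for t_idx, (t1, t2) in enumerate(self.genotypes):
                for o_idx, (o1, o2) in enumerate(self.genotypes):
                    val = e1[o1, t1] * e1[o2, t2]
                    if o1 != o2:
                        val += e1[o2, t1] * e1[o1, t2]
                    e[o_idx, t_idx] = val
            j0 = e @ j0 @ e.T
            j1 = e @ j1 @ e.T
            j2 = e @ j2 @ e.T
        self.joint = {0: j0, 1: j1, 2: j2}
        self.m_cat = {c: k0 * j0 + k1 * j1 + k2 * j2
                      for c, (k0, k1, k2) in _KCOEF.items()}

    def genotype_index(self, a: int, b: int) -> int:
        i = self.alleles.index(a)
        j = self.alleles.index(b)
        return self.gindex[(min(i, j), max(i, j))]


class PanelModel:
    """Per-locus models for a genotype panel; maps calls to genotype indices."""

    def __init__(self, table: GenotypeTable,
                 freqs: dict[str, dict[int, float]] | None = None,
                 epsilon: float = 0.001, floor: float = FREQ_FLOOR):
        if freqs is None:
            freqs = {l: table.allele_frequencies(l, floor=floor)
                     for l in table.loci}
        self.loci = list(table.loci)
        self.models = {}
        for locus in self.loci:
            f = dict(freqs[locus])
            # floor alleles present in the data but absent from freqs
            observed = set(table.allele_counts(locus))
            for a in observed - set(f):
                f[a] = floor
            tot = sum(f.values())
            f = {a: v / tot for a, v in f.items()}
            if not f:
                raise ValueError(f"no allele frequencies for locus {locus}")
            self.models[locus] = LocusModel(f, epsilon)
        # genotype index per individual per locus; -1 where missing
        n = table.n_individuals
        self.gidx = np.full((n, len(self.loci)), -1, dtype=np.int64)
        for j, locus in enumerate(self.loci):
            lm = self.models[locus]
            for i in range(n):
                a, b = table.calls[i, table.locus_index(locus)]
                if a != MISSING:
                    self.gidx[i, j] = lm.genotype_index(int(a), int(b))


def pair_likelihood(g1: dict[str, tuple[int, int]], g2: dict[str, tuple[int, int]],
                    freqs: dict[str, dict[int, float]], category: str,
                    epsilon: float = 0.0) -> float:
    """Multilocus log-likelihood of one relationship category for a pair.

    ``g1``/``g2`` map locus -> unordered allele pair; loci missing from
    either genotype are skipped.  Returns -inf for an excluded category
    (e.g. PO with no shared allele at eps = 0).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category}")
    total = 0.0
    for locus, call1 in g1.items():
        if locus not in g2 or locus not in freqs:
            continue
        lm = LocusModel(freqs[locus], epsilon)
        try:
            i1 = lm.genotype_index(*call1)
            i2 = lm.genotype_index(*g2[locus])
        except ValueError as exc:
            raise ValueError(
                f"allele absent from freqs at {locus}: {exc}") from exc
        val = lm.m_cat[category][i1, i2]
        if val <= 0:
            return -math.inf
        total += math.log(val)
    return total


def _pair_logliks(panel: PanelModel, idx1: np.ndarray, idx2: np.ndarray
                  ) -> dict[str, np.ndarray]:
    """Vectorized per-category log-likelihoods for arrays of pair indices."""
    out = {c: np.zeros(len(idx1)) for c in CATEGORIES}
    for j, locus in enumerate(panel.loci):
        g1 = panel.gidx[idx1, j]
        g2 = panel.gidx[idx2, j]
        ok = (g1 >= 0) & (g2 >= 0)
        if not np.any(ok):
            continue
        for c in CATEGORIES:
            vals = panel.models[locus].m_cat[c][g1[ok], g2[ok]]
            with np.errstate(divide="ignore"):
                out[c][ok] += np.log(vals)
    return out


def _posteriors(logliks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    mat = np.stack([logliks[c] for c in CATEGORIES])  # uniform category prior
    mx = mat.max(axis=0)
    w = np.exp(mat - mx)
    w /= w.sum(axis=0)
    return {c: w[i] for i, c in enumerate(CATEGORIES)}


def classify_pairs(table: GenotypeTable,
                   freqs: dict[str, dict[int, float]] | None = None,
                   epsilon: float = 0.001, threshold: float = 0.9,
                   replicates: int = 3, seeds: list[int] | None = None
                   ) -> list[RelationshipCall]:
    """Classify all pairs and mark supported first-order dyads.

    Pairwise posteriors are deterministic; the ``replicates`` seeded runs
    exercise only the greedy sibship-refinement scan order.  A pair is
    supported iff its first-order posterior exceeds ``threshold`` and the
    refinement retains it in every replicate.  Identical genotype vectors
    are flagged as duplicates and excluded from the dyad list.
    """
    if table.n_individuals < 2:
        raise ValueError("need at least two individuals")
    if seeds is None:
        seeds = list(range(replicates))
    if len(seeds) != replicates:
        raise ValueError("need one seed per replicate")
    panel = PanelModel(table, freqs, epsilon)
    n = table.n_individuals
    i1, i2 = np.triu_indices(n, k=1)
    logliks = _pair_logliks(panel, i1, i2)
    post = _posteriors(logliks)
    fo = post["PO"] + post["FS"]

    # duplicate guard: identical genotypes at every locus scored in both
    both = (panel.gidx[i1] >= 0) & (panel.gidx[i2] >= 0)
    same = (panel.gidx[i1] == panel.gidx[i2]) | ~both
    dup = same.all(axis=1) & (both.sum(axis=1) > 0)

    calls = []
    cat_order = list(CATEGORIES)
    for t in range(len(i1)):
        posts = {c: float(post[c][t]) for c in cat_order}
        calls.append(RelationshipCall(
            pair=(table.individuals[i1[t]], table.individuals[i2[t]]),
            category=max(posts, key=posts.get),
            posteriors=posts,
            logliks={c: float(logliks[c][t]) for c in cat_order},
            first_order_posterior=float(fo[t]),
            duplicate=bool(dup[t])))

    candidates = [t for t in range(len(calls))
                  if calls[t].first_order_posterior > threshold
                  and not calls[t].duplicate]
    ll_fo = np.maximum(logliks["PO"], logliks["FS"])
    ll_u = logliks["U"]
    pair_lookup = {(int(i1[t]), int(i2[t])): t for t in range(len(i1))}

    def fo_minus_u(a: int, b: int) -> float:
        t = pair_lookup[(min(a, b), max(a, b))]
        return float(ll_fo[t] - ll_u[t])

    kept_in_all = set(candidates)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        order = list(candidates)
        rng.shuffle(order)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        groups: dict[int, list[int]] = {}
        accepted: set[int] = set()
        for t in order:
            a, b = int(i1[t]), int(i2[t])
            ra, rb = find(a), find(b)
            if ra == rb:
                accepted.add(t)
                continue
            ga = groups.get(ra, [a])
            gb = groups.get(rb, [b])
            delta = sum(fo_minus_u(u, v) for u in ga for v in gb)
            if delta > 0:
                parent[ra] = rb
                groups[rb] = ga + gb
                groups.pop(ra, None)
                accepted.add(t)
        kept_in_all &= accepted
    for t in kept_in_all:
        calls[t].supported = True
    return calls


def supported_dyads(calls: list[RelationshipCall]) -> list[RelativeDyad]:
    return [RelativeDyad(c.pair[0], c.pair[1], c.first_order_posterior)
            for c in calls if c.supported]


# ---------------------------------------------------------------------------
# Accuracy simulation
# ---------------------------------------------------------------------------

def _draw_genotype(p: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    a, b = rng.choice(len(p), size=2, p=p)
    return int(a), int(b)


def _apply_error(allele: int, k: int, epsilon: float,
                 rng: np.random.Generator) -> int:
    if epsilon > 0 and k > 1 and rng.random() < epsilon:
        other = rng.integers(0, k - 1)
        return int(other if other < allele else other + 1)
    return allele


def _simulate_dyad(category: str, ps: list[np.ndarray], epsilon: float,
                   rng: np.random.Generator) -> tuple[list, list]:
    """Mendelian simulation of one dyad's observed multilocus genotypes."""
    g1, g2 = [], []
    for p in ps:
        k = len(p)
        f = _draw_genotype(p, rng)   # father
        m = _draw_genotype(p, rng)   # mother
        if category == "PO":
            o = (f[rng.integers(2)], _draw_genotype(p, rng)[0])
            a, b = f, o
        elif category == "FS":
            a = (f[rng.integers(2)], m[rng.integers(2)])
            b = (f[rng.integers(2)], m[rng.integers(2)])
        elif category == "HS":
            m2 = _draw_genotype(p, rng)
            a = (f[rng.integers(2)], m[rng.integers(2)])
            b = (f[rng.integers(2)], m2[rng.integers(2)])
        else:
            a = _draw_genotype(p, rng)
            b = _draw_genotype(p, rng)
        a = tuple(sorted(_apply_error(x, k, epsilon, rng) for x in a))
        b = tuple(sorted(_apply_error(x, k, epsilon, rng) for x in b))
        g1.append(a)
        g2.append(b)
    return g1, g2


def simulate_assignment_accuracy(freqs: dict[str, dict[int, float]],
                                 panel: list[str] | None = None,
                                 epsilon: float = 0.001,
                                 n_dyads: int = 500, replicates: int = 5,
                                 seed: int = 0) -> ConfusionSummary:
    """True-vs-inferred classification proportions from simulated dyads.

    Per replicate, ``n_dyads`` dyads per category are drawn under HWE from
    ``freqs``, related genotypes produced by Mendelian transmission, the
    error process applied, and each pair classified by maximum posterior.
    """
    loci = panel if panel is not None else sorted(freqs)
    if not loci:
        raise ValueError("empty locus panel")
    lms = {l: LocusModel(freqs[l], epsilon) for l in loci}
    ps = [lms[l].p for l in loci]
    seeds = [(seed * 31 + r) % (2 ** 31) for r in range(replicates)]
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        for true_cat in CATEGORIES:
            for _ in range(n_dyads):
                g1, g2 = _simulate_dyad(true_cat, ps, epsilon, rng)
                ll = {c: 0.0 for c in CATEGORIES}
                for (a, b), l in zip(zip(g1, g2), loci):
                    lm = lms[l]
                    ia = lm.gindex[a]
                    ib = lm.gindex[b]
                    for c in CATEGORIES:
                        v = lm.m_cat[c][ia, ib]
                        ll[c] += math.log(v) if v > 0 else -math.inf
                mx = max(ll.values())
                w = {c: math.exp(v - mx) for c, v in ll.items()}
                tot = sum(w.values())
                post = {c: v / tot for c, v in w.items()}
                counts.loc[true_cat, max(post, key=post.get)] += 1
    props = counts.div(counts.sum(axis=1), axis=0)
    return ConfusionSummary(props, counts, replicates, seeds)


# ---------------------------------------------------------------------------
# Dyad geography summaries
# ---------------------------------------------------------------------------

def summarize_dyads(dyads: list[RelativeDyad]) -> dict[str, float]:
    """Mean/median/min/max of each distance type plus cross-aggregation count."""
    if not dyads:
        raise ValueError("no dyads to summarize")
    out: dict[str, float] = {"n": float(len(dyads))}
    for attr, prefix in (("euclid_m", "euclid"), ("lcp_m", "lcp")):
        vals = np.array([getattr(d, attr) for d in dyads
                         if getattr(d, attr) is not None], dtype=float)
        if vals.size == 0:
            continue
        out[f"{prefix}_mean_m"] = float(vals.mean())
        out[f"{prefix}_median_m"] = float(np.median(vals))
        out[f"{prefix}_min_m"] = float(vals.min())
        out[f"{prefix}_max_m"] = float(vals.max())
    out["cross_aggregation"] = float(sum(d.cross_aggregation for d in dyads))
    return out


def dyads_to_frame(dyads: list[RelativeDyad]) -> pd.DataFrame:
    return pd.DataFrame([{
        "prob": d.probability, "euclid_m": d.euclid_m, "lcp_m": d.lcp_m,
        "id1": d.id1, "region1": d.region1, "id2": d.id2, "region2": d.region2,
    } for d in dyads])
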