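"""Genotype containers, file formats and data-quality statistics.

Diploid microsatellite genotypes are held in a :class:`GenotypeTable`:
individuals x loci, each call an unordered pair of positive integer allele
codes or missing.  The module reads and writes the GENEPOP dialect (2- and
3-digit allele encodings) and a flat CSV dialect, and provides the QC
statistics used to screen a microsatellite panel before population-genetic
analysis: the duplicate-genotyping error rate, exact tests for
Hardy-Weinberg equilibrium (Guo-Thompson style), a genotypic
linkage-disequilibrium permutation screen, and a per-locus HWE filter.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

#: internal sentinel for a missing allele call (never a legal allele code)
MISSING = -1

_SEXES = {"M", "F", "unknown"}


class PValue(float):
    """A p-value with provenance: ``method`` and, for Monte Carlo, ``se``."""

    method: str
    se: float | None

    def __new__(cls, value: float, method: str = "enumeration", se: float | None = None):
        obj = super().__new__(cls, value)
        obj.method = method
        obj.se = se
        return obj


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with optional group labels.

    Parameters
    ----------
    individuals
        Unique sample identifiers (band numbers).
    loci
        Unique locus names.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele codes
        are positive, missing calls are ``MISSING`` in both slots.
    aggregations
        Optional per-individual group label, aligned with ``individuals``.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    aggregations: list[str] | None = None

    def __post_init__(self) -> None:
        self.individuals = [str(i) for i in self.individuals]
        self.loci = [str(l) for l in self.loci]
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("calls shape does not match individuals x loci x 2")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual IDs must be unique")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        miss = self.calls == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise ValueError("missing calls must be all-or-nothing per locus")
        if np.any((self.calls <= 0) & ~miss):
            raise ValueError("allele codes must be positive integers")
        if self.aggregations is not None and len(self.aggregations) != len(self.individuals):
            raise ValueError("aggregations must align with individuals")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def index_of(self, individual: str) -> int:
        return self.individuals.index(str(individual))

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def missing_fraction(self) -> float:
        """Fraction of (individual, locus) calls that are missing."""
        return float(np.mean(self.calls[..., 0] == MISSING))

    def subset_individuals(self, ids: list[str]) -> "GenotypeTable":
        idx = [self.index_of(i) for i in ids]
        aggs = [self.aggregations[i] for i in idx] if self.aggregations else None
        return GenotypeTable([self.individuals[i] for i in idx], list(self.loci),
                             self.calls[idx], aggs)

    def subset_loci(self, loci: list[str]) -> "GenotypeTable":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeTable(list(self.individuals), [self.loci[i] for i in idx],
                             self.calls[:, idx], self.aggregations)

    def group_members(self) -> dict[str, list[str]]:
        """Map aggregation label -> member IDs (insertion order preserved)."""
        if self.aggregations is None:
            raise ValueError("table has no aggregation labels")
        out: dict[str, list[str]] = {}
        for ind, agg in zip(self.individuals, self.aggregations):
            out.setdefault(agg, []).append(ind)
        return out

    def allele_counts(self, locus: str, individuals: list[str] | None = None) -> dict[int, int]:
        """Gene-copy counts per allele at ``locus`` (missing calls skipped)."""
        j = self.locus_index(locus)
        if individuals is None:
            calls = self.calls[:, j]
        else:
            calls = self.calls[[self.index_of(i) for i in individuals], j]
        flat = calls.reshape(-1)
        flat = flat[flat != MISSING]
        vals, cnts = np.unique(flat, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnts)}

    def allele_frequencies(self, locus: str, individuals: list[str] | None = None,
                           floor: float = 0.0) -> dict[int, float]:
        counts = self.allele_counts(locus, individuals)
        total = sum(counts.values())
        if total == 0:
            return {}
        freqs = {a: c / total for a, c in counts.items()}
        if floor > 0:
            freqs = {a: max(f, floor) for a, f in freqs.items()}
            s = sum(freqs.values())
            freqs = {a: f / s for a, f in freqs.items()}
        return freqs

    def genotype_counts(self, locus: str, individuals: list[str] | None = None
                        ) -> dict[tuple[int, int], int]:
        """Unordered genotype counts ``{(lo, hi): n}`` at one locus."""
        j = self.locus_index(locus)
        if individuals is None:
            calls = self.calls[:, j]
        else:
            calls = self.calls[[self.index_of(i) for i in individuals], j]
        out: dict[tuple[int, int], int] = {}
        for a, b in calls:
            if a == MISSING:
                continue
            key = (int(min(a, b)), int(max(a, b)))
            out[key] = out.get(key, 0) + 1
        return out


@dataclass
class SampleMetadata:
    """Per-individual capture metadata: planar coordinates (m), sex, group."""

    id: str
    x: float
    y: float
    sex: str = "unknown"
    aggregation: str | None = None

    def __post_init__(self) -> None:
        self.id = str(self.id)
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"coordinates for {self.id} must be finite")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}")


@dataclass
class QCReport:
    missing_fraction: float
    error_rate: float | None
    hwe_pvalues: dict[str, dict[str, float]]  # locus -> aggregation -> p
    failed_loci: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# GENEPOP and CSV I/O
# ---------------------------------------------------------------------------

def read_genepop(path) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit alleles; 000/000000 = missing).

    Each POP block becomes one aggregation, labelled ``pop_1 .. pop_K``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty GENEPOP file")
    # title line then locus names until the first POP keyword
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        part = lines[i].strip()
        if part:
            loci.extend(p.strip() for p in part.split(",") if p.strip())
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: no POP block found (line {i})")
    individuals: list[str] = []
    aggregations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop += 1
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise ValueError(f"{path}:{i + 1}: malformed individual line (no comma)")
        name, geno = line.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"{path}:{i + 1}: expected {len(loci)} genotype fields, got {len(fields)}")
        row = []
        for f in fields:
            if len(f) not in (4, 6):
                raise ValueError(f"{path}:{i + 1}: bad genotype field '{f}'")
            w = len(f) // 2
            if width is None:
                width = w
            elif w != width:
                raise ValueError(f"{path}:{i + 1}: inconsistent allele-code width")
            a, b = int(f[:w]), int(f[w:])
            if a == 0 or b == 0:
                row.append((MISSING, MISSING))
            else:
                row.append((a, b))
        individuals.append(name.strip())
        aggregations.append(f"pop_{pop}")
        rows.append(row)
        i += 1
    calls = np.array(rows, dtype=np.int32).reshape(len(rows), len(loci), 2)
    return GenotypeTable(individuals, loci, calls, aggregations)


def write_genepop(table: GenotypeTable, path, title: str = "kinscape export",
                  width: int = 3) -> None:
    """Write GENEPOP with the given allele-code width (2 or 3 digits)."""
    if width not in (2, 3):
        raise ValueError("width must be 2 or 3")
    valid = table.calls[table.calls != MISSING]
    if valid.size and valid.max() >= 10 ** width:
        raise ValueError(f"allele codes exceed {width}-digit encoding")
    groups = (table.group_members() if table.aggregations is not None
              else {"pop_1": list(table.individuals)})
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for members in groups.values():
            fh.write("POP\n")
            for ind in members:
                row = table.calls[table.index_of(ind)]
                fields = []
                for a, b in row:
                    if a == MISSING:
                        fields.append("0" * (2 * width))
                    else:
                        fields.append(f"{a:0{width}d}{b:0{width}d}")
                fh.write(f"{ind}, " + " ".join(fields) + "\n")


def read_genotype_csv(path) -> GenotypeTable:
    """Read the CSV dialect: one row per individual, columns locus_1/locus_2."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("genotype CSV must have an 'id' column")
    loci = []
    for col in df.columns:
        if col.endswith("_1"):
            base = col[:-2]
            if base + "_2" not in df.columns:
                raise ValueError(f"missing paired column {base}_2")
            loci.append(base)
    agg = df["aggregation"].astype(str).tolist() if "aggregation" in df.columns else None
    calls = np.full((len(df), len(loci), 2), MISSING, dtype=np.int32)
    for j, locus in enumerate(loci):
        a = df[locus + "_1"].fillna(0).to_numpy(dtype=float).astype(np.int32)
        b = df[locus + "_2"].fillna(0).to_numpy(dtype=float).astype(np.int32)
        ok = (a > 0) & (b > 0)
        calls[ok, j, 0] = a[ok]
        calls[ok, j, 1] = b[ok]
    return GenotypeTable(df["id"].tolist(), loci, calls, agg)


def write_genotype_csv(table: GenotypeTable, path) -> None:
    import pandas as pd

    data: dict[str, list] = {"id": table.individuals}
    if table.aggregations is not None:
        data["aggregation"] = table.aggregations
    for j, locus in enumerate(table.loci):
        a = table.calls[:, j, 0]
        b = table.calls[:, j, 1]
        data[locus + "_1"] = np.where(a == MISSING, 0, a)
        data[locus + "_2"] = np.where(b == MISSING, 0, b)
    pd.DataFrame(data).to_csv(path, index=False)


def read_metadata_csv(path) -> dict[str, SampleMetadata]:
    import pandas as pd

    df = pd.read_csv(path, dtype={"id": str})
    out = {}
    for rec in df.to_dict("records"):
        agg = rec.get("aggregation")
        if agg is not None and (isinstance(agg, float) and math.isnan(agg)):
            agg = None
        out[str(rec["id"])] = SampleMetadata(
            id=str(rec["id"]), x=float(rec["x"]), y=float(rec["y"]),
            sex=str(rec.get("sex", "unknown")), aggregation=agg)
    return out


def write_metadata_csv(meta: dict[str, SampleMetadata], path) -> None:
    import pandas as pd

    pd.DataFrame([{"id": m.id, "x": m.x, "y": m.y, "sex": m.sex,
                   "aggregation": m.aggregation} for m in meta.values()]
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def duplicate_error_rate(table: GenotypeTable,
                         replicate_pairs: list[tuple[str, str]]) -> float:
    """Per-allele mismatch rate among re-genotyped duplicate samples.

    Loci missing in either replicate are skipped; within a call, allele order
    is ignored (multiset comparison).
    """
    if not replicate_pairs:
        raise ValueError("at least one replicate pair is required")
    mismatches = 0
    compared = 0
    for id1, id2 in replicate_pairs:
        r1 = table.calls[table.index_of(id1)]
        r2 = table.calls[table.index_of(id2)]
        for (a1, b1), (a2, b2) in zip(r1, r2):
            if a1 == MISSING or a2 == MISSING:
                continue
            g1 = sorted((int(a1), int(b1)))
            g2 = sorted((int(a2), int(b2)))
            # multiset overlap of two 2-element multisets
            overlap = 0
            pool = list(g2)
            for x in g1:
                if x in pool:
                    pool.remove(x)
                    overlap += 1
            mismatches += 2 - overlap
            compared += 2
    if compared == 0:
        raise ValueError("no comparable alleles among replicate pairs")
    return mismatches / compared


def _table_logprob(het: int, n_ind: int, n_alleles_fact: float,
                   log2n_fact: float, sum_log_nij_fact: float) -> float:
    # conditional probability of a genotype array given allele counts (Levene)
    return (gammaln(n_ind + 1) + het * math.log(2.0) + n_alleles_fact
            - log2n_fact - sum_log_nij_fact)


def _genotype_table_logp(counts: dict[tuple[int, int], int],
                         allele_counts: dict[int, int]) -> float:
    n = sum(counts.values())
    het = sum(c for (a, b), c in counts.items() if a != b)
    na = sum(gammaln(c + 1) for c in allele_counts.values())
    return _table_logprob(het, n, na, gammaln(2 * n + 1),
                          sum(gammaln(c + 1) for c in counts.values()))


def _enumerate_hwe_tables(allele_counts: list[int], cap: int):
    """Yield genotype tables (dict pair->count) with the given allele counts.

    Raises OverflowError when more than ``cap`` tables exist.
    """
    k = len(allele_counts)
    seen = 0

    def rec(i: int, rem: list[int], acc: dict):
        nonlocal seen
        if i == k:
            if all(r == 0 for r in rem):
                seen += 1
                if seen > cap:
                    raise OverflowError("table space exceeds enumeration cap")
                yield dict(acc)
            return
        # distribute rem[i] copies of allele i among (i,i) and (i,j>i)
        others = [j for j in range(i + 1, k)]

        def assign(pos: int, left: int):
            if pos == len(others):
                if left % 2 == 0:
                    acc[(i, i)] = left // 2
                    saved, rem[i] = rem[i], 0  # all copies of i consumed
                    yield from rec(i + 1, rem, acc)
                    rem[i] = saved
                    del acc[(i, i)]
                return
            j = others[pos]
            for nij in range(min(left, rem[j]) + 1):
                acc[(i, j)] = nij
                rem[j] -= nij
                yield from assign(pos + 1, left - nij)
                rem[j] += nij
                del acc[(i, j)]

        yield from assign(0, rem[i])

    yield from rec(0, list(allele_counts), {})


def hwe_exact_test(counts: dict[tuple[int, int], int],
                   method: str = "auto",
                   chain: tuple[int, int, int] = (10_000, 100, 5_000),
                   seed: int | None = None,
                   enumeration_cap: int = 1_000_000) -> PValue:
    """Exact probability test for Hardy-Weinberg equilibrium at one locus.

    ``counts`` maps unordered genotype ``(a, b)`` to its count in one group.
    The p-value is the total conditional probability (given allele counts) of
    genotype arrays no more probable than the observed one.  Full enumeration
    is used while the table space stays below ``enumeration_cap``; otherwise a
    Markov chain over gene-copy pairings (random transpositions, uniform over
    pairings, hence visiting tables in proportion to their conditional
    probability) estimates the same tail sum.  The chain tuple is
    ``(burnin, batches, iterations_per_batch)``; a seed is then required.

    A monomorphic locus returns p = 1 (single possible table).
    """
    counts = {(min(a, b), max(a, b)): int(c) for (a, b), c in counts.items() if c > 0}
    n = sum(counts.values())
    if n < 2:
        raise ValueError("need at least 2 genotyped individuals")
    allele_counts: dict[int, int] = {}
    for (a, b), c in counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    alleles = sorted(allele_counts)
    if len(alleles) < 2:
        return PValue(1.0, method="degenerate")
    remap = {a: i for i, a in enumerate(alleles)}
    obs = {(remap[a], remap[b]): c for (a, b), c in counts.items()}
    obs = {(min(i, j), max(i, j)): c for (i, j), c in obs.items()}
    ac = [allele_counts[a] for a in alleles]
    logp_obs = _genotype_table_logp(obs, dict(enumerate(ac)))
    tol = 1e-9

    if method in ("auto", "enumeration"):
        try:
            total = 0.0
            for tbl in _enumerate_hwe_tables(
                    ac, enumeration_cap if method == "auto" else 10 ** 12):
                lp = _genotype_table_logp(tbl, dict(enumerate(ac)))
                if lp <= logp_obs + tol:
                    total += math.exp(lp)
            return PValue(min(total, 1.0), method="enumeration")
        except OverflowError:
            if method == "enumeration":
                raise

    if seed is None:
        raise ValueError("seed is required for the MCMC exact test")
    burnin, batches, iters = chain
    rng = np.random.default_rng(seed)
    # gene-copy vector paired consecutively; start at the observed pairing
    copies: list[int] = []
    for (i, j), c in obs.items():
        copies.extend([i, j] * c)
    copies = np.array(copies, dtype=np.int64)
    m = copies.size
    tab = np.zeros((len(ac), len(ac)), dtype=np.int64)
    for t in range(n):
        i, j = sorted((copies[2 * t], copies[2 * t + 1]))
        tab[i, j] += 1
    na_fact = sum(gammaln(c + 1) for c in ac)
    log2n_fact = gammaln(2 * n + 1)
    lgf = gammaln(np.arange(n + 2))  # log-factorial lookup
    log2 = math.log(2.0)

    state = {"sum_lgf": float(sum(gammaln(c + 1) for c in tab[tab > 0])),
             "het": int(tab.sum() - np.trace(tab))}

    def current_logp() -> float:
        return _table_logprob(state["het"], n, na_fact, log2n_fact,
                              state["sum_lgf"])

    logp = current_logp()
    batch_means = []
    us = rng.integers(0, m, size=burnin + batches * iters)
    vs = rng.integers(0, m, size=burnin + batches * iters)
    step = 0

    def _remove(i: int, j: int) -> None:
        c = tab[i, j]
        state["sum_lgf"] += lgf[c] - lgf[c + 1]
        tab[i, j] = c - 1
        if i != j:
            state["het"] -= 1

    def _add(i: int, j: int) -> None:
        c = tab[i, j]
        state["sum_lgf"] += lgf[c + 2] - lgf[c + 1]
        tab[i, j] = c + 1
        if i != j:
            state["het"] += 1

    def swap(u: int, v: int) -> None:
        nonlocal logp
        pu, pv = u // 2, v // 2
        if pu == pv or copies[u] == copies[v]:
            return
        for p in (pu, pv):
            i, j = sorted((copies[2 * p], copies[2 * p + 1]))
            _remove(i, j)
        copies[u], copies[v] = copies[v], copies[u]
        for p in (pu, pv):
            i, j = sorted((copies[2 * p], copies[2 * p + 1]))
            _add(i, j)
        logp = current_logp()

    for _ in range(burnin):
        swap(int(us[step]), int(vs[step]))
        step += 1
    for _ in range(batches):
        hits = 0
        for _ in range(iters):
            swap(int(us[step]), int(vs[step]))
            step += 1
            if logp <= logp_obs + tol:
                hits += 1
        batch_means.append(hits / iters)
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(len(batch_means)))
    return PValue(max(p, 1.0 / (batches * iters)), method="mcmc", se=se)


def filter_loci(table: GenotypeTable, hwe_matrix: dict[str, dict[str, float]],
                alpha: float = 0.05, fail_fraction: float = 0.5
                ) -> tuple[GenotypeTable, list[str]]:
    """Drop loci out of HWE (p < alpha) in >= ``fail_fraction`` of groups."""
    failed = []
    for locus in table.loci:
        ps = hwe_matrix.get(locus)
        if ps is None:
            raise ValueError(f"hwe_matrix does not cover locus {locus}")
        sig = sum(1 for p in ps.values() if p < alpha)
        if ps and sig / len(ps) >= fail_fraction:
            failed.append(locus)
    kept = [l for l in table.loci if l not in failed]
    if not kept:
        raise ValueError("all loci failed the HWE filter")
    return table.subset_loci(kept), failed


def ld_permutation_test(table: GenotypeTable, locus1: str, locus2: str,
                        permutations: int = 10_000, seed: int | None = None) -> PValue:
    """Genotypic linkage-disequilibrium permutation test for a locus pair.

    Statistic is the G log-likelihood of association of the joint genotype
    table, summed over aggregations; one locus's genotypes are permuted
    within each aggregation.  A simplification of the GENEPOP genotypic LD
    test (documented as such).
    """
    rng = np.random.default_rng(seed)
    j1, j2 = table.locus_index(locus1), table.locus_index(locus2)
    groups = (table.group_members() if table.aggregations is not None
              else {"all": list(table.individuals)})

    def gstat(g1: np.ndarray, g2: np.ndarray) -> float:
        # joint genotype contingency table G statistic
        pairs1 = [tuple(sorted(map(int, g))) for g in g1]
        pairs2 = [tuple(sorted(map(int, g))) for g in g2]
        u1 = {g: i for i, g in enumerate(sorted(set(pairs1)))}
        u2 = {g: i for i, g in enumerate(sorted(set(pairs2)))}
        tab = np.zeros((len(u1), len(u2)))
        for a, b in zip(pairs1, pairs2):
            tab[u1[a], u2[b]] += 1
        tot = tab.sum()
        exp = np.outer(tab.sum(1), tab.sum(0)) / tot
        nz = tab > 0
        return float(2 * np.sum(tab[nz] * np.log(tab[nz] / exp[nz])))

    obs = 0.0
    group_calls = []
    for members in groups.values():
        idx = [table.index_of(i) for i in members]
        g1 = table.calls[idx, j1]
        g2 = table.calls[idx, j2]
        ok = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
        g1, g2 = g1[ok], g2[ok]
        if len(g1) >= 2:
            obs += gstat(g1, g2)
            group_calls.append((g1, g2))
    if not group_calls:
        return PValue(1.0, method="degenerate")
    hits = 0
    for _ in range(permutations):
        stat = 0.0
        for g1, g2 in group_calls:
            stat += gstat(g1, g2[rng.permutation(len(g2))])
        if stat >= obs - 1e-12:
            hits += 1
    return PValue((hits + 1) / (permutations + 1), method="permutation")


def qc_report(table: GenotypeTable,
              replicate_pairs: list[tuple[str, str]] | None = None,
              alpha: float = 0.05, fail_fraction: float = 0.5,
              seed: int | None = 0,
              min_group_size: int = 5,
              enumeration_cap: int = 500,
              chain: tuple[int, int, int] = (1_000, 10, 200)) -> QCReport:
    """Missing-data fraction, duplicate error rate and per-locus HWE screen.

    The HWE tests use a smaller enumeration cap and shorter chains than the
    standalone test defaults: the screen is a 0.05-level filter over many
    locus x group cells, where Monte Carlo p-value noise of ~0.01 is
    immaterial.
    """
    err = duplicate_error_rate(table, replicate_pairs) if replicate_pairs else None
    groups = (table.group_members() if table.aggregations is not None
              else {"all": list(table.individuals)})
    hwe: dict[str, dict[str, float]] = {}
    for locus in table.loci:
        hwe[locus] = {}
        for label, members in groups.items():
            if len(members) < min_group_size:
                continue
            counts = table.genotype_counts(locus, members)
            if sum(counts.values()) < 2:
                continue
            hwe[locus][label] = float(hwe_exact_test(
                counts, seed=seed, enumeration_cap=enumeration_cap,
                chain=chain))
    _, failed = filter_loci(table, hwe, alpha=alpha, fail_fraction=fail_fraction)
    return QCReport(table.missing_fraction(), err, hwe, failed)
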