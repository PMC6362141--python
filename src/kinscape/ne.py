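"""Effective population size: linkage-disequilibrium and sibship methods.

The LD method uses the Burrows composite disequilibrium between unlinked
locus pairs.  Under random mating the expected squared correlation in a
sample of S individuals is E[r^2 | S] = 1/S + 3.19/S^2 (S >= 30) or
0.0018 + 0.907/S + 4.44/S^2 (S < 30); subtracting it leaves the drift
signal r^2_drift, and

    Ne = (1/3 + sqrt(1/9 - 2.76 r^2_drift)) / (2 r^2_drift)

with Ne = infinity when r^2_drift <= 0 (no drift signal above sampling
noise).  The sibship method inverts the frequency of full- and half-sib
pairs among all sampled pairs: 1/Ne = (2 Q_FS + Q_HS) / 4 under random
mating.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeTable
from .kinship import RelationshipCall


@dataclass
class NeEstimate:
    method: str           # "LD" or "sibship"
    point: float          # may be math.inf
    ci_low: float
    ci_high: float
    maf: float | None = None
    s: float | None = None       # (harmonic mean) sample size
    r2_mean: float | None = None
    no_signal: bool = False      # r^2_drift <= 0 or discriminant < 0


def _expected_r2(s: float) -> float:
    if s >= 30:
        return 1.0 / s + 3.19 / s ** 2
    return 0.0018 + 0.907 / s + 4.44 / s ** 2


def _ne_from_r2drift(r2d: float) -> tuple[float, bool]:
    if r2d <= 0:
        return math.inf, True
    disc = 1.0 / 9.0 - 2.76 * r2d
    if disc < 0:
        return math.inf, True
    return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2d), False


def _burrows_r2(table: GenotypeTable, maf: float) -> tuple[list[tuple[int, float, int]], float]:
    """Per-locus-pair mean Burrows r^2.

    Returns ([(n_allele_pairs, mean_r2, S)], harmonic-mean S).  For each
    locus pair and each allele pair (after the MAF screen), the composite
    disequilibrium Delta is estimated from dosages with the S/(S-1)
    correction and squared over the product of allele variances.
    """
    loci = table.loci
    n_ind = table.n_individuals
    # dosage matrices and missingness per locus
    dosages: dict[str, np.ndarray] = {}
    present: dict[str, np.ndarray] = {}
    alleles_used: dict[str, list[int]] = {}
    for j, locus in enumerate(loci):
        calls = table.calls[:, j]
        ok = calls[:, 0] != MISSING
        freqs = table.allele_frequencies(locus)
        alleles = [a for a, f in sorted(freqs.items()) if f >= maf and f <= 1 - maf]
        if len(alleles) < 2:
            alleles = [a for a in alleles if freqs.get(a, 0) < 1]
        d = np.zeros((n_ind, len(alleles)))
        for ai, a in enumerate(alleles):
            d[:, ai] = (calls[:, 0] == a).astype(float) + (calls[:, 1] == a).astype(float)
        dosages[locus] = d
        present[locus] = ok
        alleles_used[locus] = alleles

    results = []
    ss = []
    for l1, l2 in itertools.combinations(loci, 2):
        if not alleles_used[l1] or not alleles_used[l2]:
            continue
        ok = present[l1] & present[l2]
        s = int(ok.sum())
        if s < 2:
            continue
        d1 = dosages[l1][ok]
        d2 = dosages[l2][ok]
        p1 = d1.mean(axis=0) / 2.0
        p2 = d2.mean(axis=0) / 2.0
        use1 = (p1 > 0) & (p1 < 1)
        use2 = (p2 > 0) & (p2 < 1)
        if not use1.any() or not use2.any():
            continue
        d1 = d1[:, use1]
        d2 = d2[:, use2]
        p1 = p1[use1]
        p2 = p2[use2]
        # Delta_AB = S/(S-1) * (mean(gA gB)/2 - 2 pA pB)
        cross = (d1.T @ d2) / s / 2.0
        delta = (s / (s - 1.0)) * (cross - 2.0 * np.outer(p1, p2))
        denom = np.outer(p1 * (1 - p1), p2 * (1 - p2))
        r2 = delta ** 2 / denom
        results.append((r2.size, float(r2.mean()), s))
        ss.append(s)
    if not results:
        raise ValueError("fewer than 2 usable loci after the MAF screen")
    harm_s = len(ss) / sum(1.0 / s for s in ss)
    return results, harm_s


def ld_ne(table: GenotypeTable, maf: float = 0.01) -> NeEstimate:
    """LD effective population size with jackknife-over-locus-pairs CI.

    Allele-pair r^2 values are averaged within each locus pair, then
    combined across locus pairs weighted by their number of independent
    allele comparisons.  The sampling expectation at the harmonic-mean
    sample size is subtracted before inverting to Ne.
    """
    pairs, harm_s = _burrows_r2(table, maf)
    if len(pairs) < 1:
        raise ValueError("no locus pairs available")
    weights = np.array([w for w, _, _ in pairs], dtype=float)
    means = np.array([m for _, m, _ in pairs])
    r2_mean = float(np.sum(weights * means) / weights.sum())
    exp_r2 = _expected_r2(harm_s)
    point, flag = _ne_from_r2drift(r2_mean - exp_r2)

    # jackknife over locus pairs on the weighted mean r^2
    if len(pairs) >= 2:
        loo = []
        wsum = weights.sum()
        tot = float(np.sum(weights * means))
        for i in range(len(pairs)):
            loo.append((tot - weights[i] * means[i]) / (wsum - weights[i]))
        loo = np.array(loo)
        n = len(loo)
        se = math.sqrt((n - 1) / n * float(np.sum((loo - loo.mean()) ** 2)))
        r2_lo = r2_mean - 1.96 * se
        r2_hi = r2_mean + 1.96 * se
        ci_high, _ = _ne_from_r2drift(r2_lo - exp_r2)
        ci_low, _ = _ne_from_r2drift(r2_hi - exp_r2)
    else:
        ci_low, ci_high = 0.0, math.inf
    return NeEstimate("LD", point, min(ci_low, point), ci_high, maf=maf,
                      s=harm_s, r2_mean=r2_mean, no_signal=flag)


def _sibship_point(n_fs: int, n_hs: int, n: int) -> tuple[float, bool]:
    npairs = n * (n - 1) // 2
    if npairs == 0:
        raise ValueError("need at least two sampled individuals")
    q = (2.0 * n_fs / npairs + n_hs / npairs) / 4.0
    if q <= 0:
        return math.inf, True
    return 1.0 / q, False


def sibship_ne(calls: list[RelationshipCall], n_sampled: int,
               bootstrap: int = 200, seed: int | None = 0,
               posterior_threshold: float = 0.9) -> NeEstimate:
    """Sibship-frequency Ne from supported FS/HS calls.

    Uses 1/Ne = (2 Q_FS + Q_HS)/4 with Q the observed sib-pair frequencies
    among all C(n, 2) sampled pairs; 95% CI by bootstrap over individuals.
    """
    sib_pairs: dict[tuple[str, str], str] = {}
    for c in calls:
        if c.duplicate:
            continue
        if c.category == "FS" and c.posteriors.get("FS", 0) > posterior_threshold:
            sib_pairs[tuple(sorted(c.pair))] = "FS"
        elif c.category == "HS" and c.posteriors.get("HS", 0) > posterior_threshold:
            sib_pairs[tuple(sorted(c.pair))] = "HS"
    ids = sorted({i for c in calls for i in c.pair})
    n_fs = sum(1 for v in sib_pairs.values() if v == "FS")
    n_hs = sum(1 for v in sib_pairs.values() if v == "HS")
    point, flag = _sibship_point(n_fs, n_hs, n_sampled)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(bootstrap):
        sample = rng.choice(len(ids), size=n_sampled, replace=True)
        chosen = [ids[i] for i in sample]
        fs = hs = 0
        for a, b in itertools.combinations(range(n_sampled), 2):
            if chosen[a] == chosen[b]:
                continue
            cat = sib_pairs.get(tuple(sorted((chosen[a], chosen[b]))))
            if cat == "FS":
                fs += 1
            elif cat == "HS":
                hs += 1
        boots.append(_sibship_point(fs, hs, n_sampled)[0])
    boots = np.array(boots)
    # order statistics only: no interpolation across infinite estimates
    ci_low = float(np.percentile(boots, 2.5, method="lower"))
    ci_high = float(np.percentile(boots, 97.5, method="higher"))
    return NeEstimate("sibship", point, min(ci_low, point),
                      max(ci_high, point), no_signal=flag)
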