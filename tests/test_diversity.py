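"""Diversity indices, relatedness, FST and isolation by distance."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from kinscape import (GenotypeTable, PairwiseMatrix, SimulationSpec,
                      mantel_ibd, mean_relatedness, pairwise_fst,
                      queller_goodnight_r, rarefied_allelic_richness,
                      simulate_island_genotypes, weir_cockerham_theta)
from kinscape.diversity import het_and_f, allelic_richness, linearized_fst


def _table(calls, groups=None):
    calls = np.asarray(calls, dtype=np.int32)
    ids = [f"i{k}" for k in range(calls.shape[0])]
    return GenotypeTable(ids, [f"L{j}" for j in range(calls.shape[1])],
                         calls, groups)


# ---------------------------------------------------------------------------
# Heterozygosity and F
# ---------------------------------------------------------------------------

def test_het_all_heterozygotes():
    t = _table([[[1, 2]], [[1, 2]], [[1, 2]], [[1, 2]]])
    ho, he, uhe, f = het_and_f(t)
    assert (ho, he, f) == (1.0, 0.5, -1.0)
    assert uhe == pytest.approx(8 / 7 * 0.5)


def test_monomorphic_locus_excluded_from_f():
    t = _table([[[1, 2], [3, 3]], [[1, 2], [3, 3]]])
    ho, he, _, f = het_and_f(t)
    assert f == -1.0          # only the polymorphic locus contributes
    assert ho == pytest.approx(0.5)   # mean over both loci
    with pytest.raises(ValueError, match="monomorphic"):
        het_and_f(_table([[[3, 3]], [[3, 3]]]))


def test_het_matches_direct_allele_count_oracle():
    rng = np.random.default_rng(5)
    calls = rng.integers(1, 4, size=(10, 1, 2))
    t = _table(calls)
    _, he, _, _ = het_and_f(t)
    flat = calls.reshape(-1)
    freqs = np.bincount(flat)[1:] / flat.size
    assert he == pytest.approx(1 - np.sum(freqs ** 2))


def test_he_invariant_under_allele_relabelling():
    rng = np.random.default_rng(6)
    calls = rng.integers(1, 5, size=(12, 2, 2)).astype(np.int32)
    t1 = _table(calls)
    relabel = {1: 7, 2: 3, 3: 9, 4: 1}
    calls2 = np.vectorize(relabel.get)(calls).astype(np.int32)
    t2 = _table(calls2)
    assert het_and_f(t1) == pytest.approx(het_and_f(t2))


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def test_rarefaction_trivial_cases():
    assert rarefied_allelic_richness({1: 10}, 4) == 1.0
    assert rarefied_allelic_richness({1: 6, 2: 4}, 10) == 2.0  # g = N


@pytest.mark.parametrize("counts,g", [
    ((6, 4), 4), ((5, 4, 3), 5), ((10, 1, 1), 6), ((3, 3, 3, 3), 7),
])
def test_rarefaction_matches_exhaustive_enumeration(counts, g):
    """Exact equality with brute-force enumeration of all C(N, g) subsamples."""
    genes = [a for a, c in enumerate(counts) for _ in range(c)]
    oracle = np.mean([len(set(sub))
                      for sub in itertools.combinations(genes, g)])
    ar = rarefied_allelic_richness(dict(enumerate(counts)), g)
    assert ar == pytest.approx(float(oracle), abs=1e-12)


def test_rarefaction_bad_g_errors():
    with pytest.raises(ValueError):
        rarefied_allelic_richness({1: 3, 2: 2}, 6)


@given(g=st.integers(min_value=1, max_value=12))
@settings(deadline=None, max_examples=12)
def test_rarefaction_monotone_in_g(g):
    counts = {1: 5, 2: 4, 3: 3}
    if g < 12:
        assert (rarefied_allelic_richness(counts, g)
                <= rarefied_allelic_richness(counts, g + 1) + 1e-12)


# ---------------------------------------------------------------------------
# Queller-Goodnight relatedness
# ---------------------------------------------------------------------------

FREQS = {"L0": {1: 0.3, 2: 0.3, 3: 0.4}, "L1": {1: 0.2, 2: 0.5, 3: 0.3}}


def test_qg_self_relatedness_is_one():
    t = _table([[[1, 2], [3, 3]]])
    assert queller_goodnight_r(t, ("i0", "i0"), FREQS) == pytest.approx(1.0)


def test_qg_no_shared_alleles_negative():
    freqs = {"L0": {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}}
    t = _table([[[1, 2]], [[3, 4]]])
    assert queller_goodnight_r(t, ("i0", "i1"), freqs) < 0


def test_qg_matches_term_by_term_oracle():
    t = _table([[[1, 2], [2, 3]], [[1, 3], [2, 2]]])

    def one_direction(gx, gy):
        num = den = 0.0
        for locus, (a, b) in gx.items():
            c, d = gy[locus]
            p = FREQS[locus]
            sim = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
            num += sim - p[a] - p[b]
            den += 1 + (a == b) - p[a] - p[b]
        return num / den

    g1 = {"L0": (1, 2), "L1": (2, 3)}
    g2 = {"L0": (1, 3), "L1": (2, 2)}
    expected = 0.5 * (one_direction(g1, g2) + one_direction(g2, g1))
    assert queller_goodnight_r(t, ("i0", "i1"), FREQS) == pytest.approx(expected)


def test_qg_population_mean_near_zero():
    """Mean pairwise r over the reference sample is ~0 when frequencies are
    estimated from that same sample."""
    spec = SimulationSpec(n_demes=1, n_per_deme=100, target_fst=0.0,
                          epsilon=0.0, n_loci=10, master_seed=9)
    t, _ = simulate_island_genotypes(spec)
    freqs = {l: t.allele_frequencies(l) for l in t.loci}
    assert abs(mean_relatedness(t, t.individuals, freqs)) < 0.02


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def test_theta_fixed_differences_is_one():
    t = _table([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]])
    theta = weir_cockerham_theta(t, [["i0", "i1"], ["i2", "i3"]])
    assert theta == pytest.approx(1.0)


def test_theta_duplicated_group_near_zero():
    rng = np.random.default_rng(2)
    calls = rng.integers(1, 6, size=(30, 5, 2)).astype(np.int32)
    calls = np.concatenate([calls, calls])
    t = _table(calls)
    theta = weir_cockerham_theta(
        t, [[f"i{k}" for k in range(30)], [f"i{k}" for k in range(30, 60)]])
    assert abs(theta) < 0.02  # identical groups: only the n-bias term remains


def test_theta_panmictic_near_zero():
    spec = SimulationSpec(n_demes=2, n_per_deme=500, n_loci=20,
                          target_fst=0.0, epsilon=0.0, master_seed=11)
    t, _ = simulate_island_genotypes(spec)
    groups = list(t.group_members().values())
    assert abs(weir_cockerham_theta(t, groups)) < 0.01


def test_theta_recovers_island_model_target():
    spec = SimulationSpec(n_demes=10, n_per_deme=200, n_loci=20,
                          target_fst=0.1, epsilon=0.0, master_seed=3)
    t, _ = simulate_island_genotypes(spec)
    theta = weir_cockerham_theta(t, list(t.group_members().values()))
    assert 0.08 <= theta <= 0.12


def test_pairwise_fst_excludes_small_groups(island_table):
    t, _, _ = island_table
    groups = t.group_members()
    label = list(groups)[0]
    groups[label] = groups[label][:1]
    with pytest.warns(UserWarning, match="below minimum"):
        mat = pairwise_fst(t, groups)
    assert label not in mat.labels


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _random_sym(n, rng):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


def test_mantel_identity_r_is_one():
    rng = np.random.default_rng(0)
    m = PairwiseMatrix(list("abcdef"), _random_sym(6, rng))
    z, r, p = mantel_ibd(m, m, permutations=999, seed=1)
    assert r == pytest.approx(1.0)
    assert p < 0.02
    assert z == pytest.approx(np.sum(m.offdiag() ** 2))


def test_mantel_matches_exhaustive_permutations():
    rng = np.random.default_rng(4)
    x = PairwiseMatrix(list("abcd"), _random_sym(4, rng))
    y = PairwiseMatrix(list("abcd"), _random_sym(4, rng))
    iu = np.triu_indices(4, 1)
    r_obs = np.corrcoef(x.values[iu], y.values[iu])[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(4)):
        xp = x.values[np.ix_(perm, perm)][iu]
        r_p = np.corrcoef(xp, y.values[iu])[0, 1]
        total += 1
        hits += r_p >= r_obs - 1e-12
    exact = hits / total
    # Monte Carlo estimate converges to the exhaustive tail probability
    _, _, p = mantel_ibd(x, y, permutations=20_000, seed=5)
    assert float(p) == pytest.approx(exact, abs=0.02)


def test_mantel_null_rejection_calibrated():
    rng = np.random.default_rng(8)
    rejections, reps = 0, 200
    labels = list("abcdefg")
    for _ in range(reps):
        x = PairwiseMatrix(labels, _random_sym(7, rng))
        y = PairwiseMatrix(labels, _random_sym(7, rng))
        _, _, p = mantel_ibd(x, y, permutations=99,
                             seed=int(rng.integers(2 ** 31)))
        rejections += p <= 0.05
    lo, hi = binom.ppf([0.005, 0.995], reps, 0.05)
    assert lo <= rejections <= hi


def test_mantel_constant_matrix_errors():
    m = PairwiseMatrix(list("abc"), np.zeros((3, 3)))
    with pytest.raises(ValueError, match="constant"):
        mantel_ibd(m, m, permutations=9, seed=0)


def test_linearized_fst():
    m = PairwiseMatrix(["a", "b"], np.array([[0, 0.2], [0.2, 0]]))
    assert linearized_fst(m).values[0, 1] == pytest.approx(0.25)
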