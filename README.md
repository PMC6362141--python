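# kinscape

Landscape population genetics for fragmented populations: did habitat loss
subdivide a population genetically, and is apparent connectivity recent
dispersal or a leftover signal of historical gene flow?

`kinscape` is a Python library built around the analysis design used for
the coastal California gnatcatcher (*Polioptila californica californica*),
a threatened, non-migratory songbird of southern California's coastal sage
scrub. It covers the full chain:

* **Genotype QC** — GENEPOP/CSV microsatellite I/O, duplicate-genotyping
  error rate, Guo–Thompson-style Hardy–Weinberg exact tests
  (enumeration + MCMC), locus filtering, genotypic LD screen.
* **Diversity** — Ho, He, F, rarefied allelic richness
  Ar = Σᵢ[1 − C(N−Nᵢ,g)/C(N,g)], Queller–Goodnight relatedness,
  Weir–Cockerham θ, Mantel isolation-by-distance.
* **Population delimitation** — pairwise genic exact tests on allele-count
  tables (probability method, enumeration or Monte Carlo), Fisher-combined
  across loci with a 10⁻⁴ floor, aggregations grouped when combined
  p > 0.01.
* **Kinship & dispersal** — pairwise IBD-coefficient likelihoods
  (L = k₀P₀ + k₁P₁ + k₂P₂ over {U, PO, FS, HS}) with an analytic
  genotyping-error model; supported first-order dyads mapped to Euclidean
  and least-cost distances.
* **Effective population size** — the linkage-disequilibrium method
  (Burrows r², Ne = (1/3 + √(1/9 − 2.76·r²_drift))/(2·r²_drift)) and the
  sibship-frequency method (1/Ne = (2Q̃_FS + Q̃_HS)/4).
* **Habitat suitability** — partitioned Mahalanobis D² model with spatial
  bootstrap and PCA averaging; HSI ∈ [0,1]; ESRI ASCII rasters.
* **Landscape** — friction = 1/HSI, Dijkstra least-cost paths, percent
  suitable habitat in 5/30 km buffers.
* **Diversity vs habitat** — correlation screening, Moran's I, and linear /
  logarithmic (y = a + b·ln x) fits.
* **Synthetic data** — island-model genotypes (Balding–Nichols at a target
  FST), planted relative dyads, Wright–Fisher populations, and landscapes
  with known suitability, so every stage is testable without downloads.

Two small published summary tables for the gnatcatcher are bundled: the 34
supported first-order relative dyads with distances, and the 18-aggregation
diversity/habitat table.

## Worked example

```python
from kinscape import load_ccg_dyads, summarize_dyads, load_ccg_diversity, \
    fit_diversity_models

s = summarize_dyads(load_ccg_dyads())
print(f"Euclidean: mean {s['euclid_mean_m']/1000:.1f} km, "
      f"median {s['euclid_median_m']/1000:.1f} km, "
      f"max {s['euclid_max_m']/1000:.0f} km; "
      f"cross-aggregation pairs: {s['cross_aggregation']:.0f}/34")

df = load_ccg_diversity()
log = {f.form: f for f in
       fit_diversity_models(df.pct_suitable_30km, df.ar)}["logarithmic"]
print(f"Ar = {log.intercept:.2f} + {log.slope:.2f} ln(pct30), R² = {log.r2:.2f}")
```

prints

```
Euclidean: mean 29.9 km, median 5.0 km, max 133 km; cross-aggregation pairs: 13/34
Ar = 3.81 + 0.35 ln(pct30), R² = 0.53
```

First-order relatives found a median 5 km but up to 133 km apart — recent
long-distance dispersal — and allelic richness rises logarithmically with
the fraction of suitable habitat within 30 km, dropping steeply below ~10%.

The `examples/` directory holds one short script per capability
(simulation, QC + diversity, delimitation, kinship + dispersal distances,
effective size, habitat + regression); each prints the numbers it computes
with a line on what they mean. A thin CLI covers the two shell entry
points: `kinscape simulate --out DIR --seed N` writes a complete synthetic
fixture bundle, and `kinscape run --manifest FILE` executes the whole
pipeline from a flat-text run manifest.

`docs/methods.md` documents the statistical models, defaults, numerical
choices and known limitations.

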