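"""Generate island-model microsatellite genotypes with a known FST.

Builds the default synthetic study: 18 local aggregations of 15 birds
genotyped at 19 loci (~10 alleles each), differentiated at a target FST of
0.1 here so the signal is visible, then verifies the realized
differentiation with the Weir-Cockerham estimator.
"""

from kinscape import (SimulationSpec, simulate_island_genotypes,
                      weir_cockerham_theta, write_genepop)

spec = SimulationSpec(target_fst=0.1, master_seed=1)
table, truth = simulate_island_genotypes(spec)
theta = weir_cockerham_theta(table, list(table.group_members().values()))

print(f"simulated {table.n_individuals} individuals, {table.n_loci} loci, "
      f"{len(table.group_members())} demes")
print(f"target FST = {spec.target_fst}, realized Weir-Cockerham theta = "
      f"{theta:.3f}")
print("theta near the target confirms the Balding-Nichols deme frequencies "
      "behave as labelled")

write_genepop(table, "island_genotypes.gen")
print("wrote island_genotypes.gen (GENEPOP, 3-digit alleles)")
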