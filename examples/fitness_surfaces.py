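"""Marginal fitness curves and genotypic fitness surfaces.

Builds the four selection models at s = 0.005, alpha = 12 and prints a few
marginal fitnesses plus the structure of each genotypic surface.  Under the
single-optimum models fitness declines as a Gaussian in distance from the
key allele size; under the periodic-optima models every multiple of alpha
is an optimum.  Dominant models put entire rows/columns of the genotype
grid at fitness 1.0 ("ridges"), additive models only the alpha/alpha peak.
"""

import numpy as np

import strsel as ss

for kind in ("ASO", "DSO", "APO", "DPO"):
    model = ss.SelectionModelSpec(kind=kind, s=0.005, alpha=12)
    w = {a: ss.marginal_fitness(model, a) for a in (6, 12, 13, 18, 24, 36)}
    print(f"{kind}: " + "  ".join(f"w({a})={v:.4f}" for a, v in w.items()))
    surf = ss.fitness_surface(model, 1, 50)
    peak = np.argwhere(surf.grid == 1.0)
    print(f"     genotypes at fitness 1.0: {len(peak)}")

print()
print("Genotype count for a locus with 8 alleles:", ss.genotype_count(8))
print("(n alleles can form n(n+1)/2 distinct unordered diploid genotypes)")
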