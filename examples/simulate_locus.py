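"""Simulate one microsatellite locus through the eight-population history.

Builds a tiny pool of starting allele-frequency distributions, runs one
forward simulation under strong additive single-optimum selection
(s = 0.015, alpha = 9) and one neutral simulation, and prints the sampled
mean allele size (M_AS), variance in allele size (V_AS) and per-population
observed heterozygosity.  Strong selection keeps the sample huddled at the
key allele size; neutral loci retain the variation of their starting AFD.

Simulations are diffusion-rescaled by a factor of 20 (Ne 10,000 -> 500,
mutation and selection scaled up accordingly) so the script runs in
seconds while preserving N*mu and N*s.
"""

import strsel as ss

pool = ss.build_afd_pool(ss.AFDPoolConfig(pool_size=50, n_haplotypes=200, seed=1))
schedule = ss.default_schedule()
mut = ss.MutationSpec.for_motif(2)  # dinucleotide

for label, model in [
    ("ASO s=0.015 alpha=9", ss.SelectionModelSpec(kind="ASO", s=0.015, alpha=9)),
    ("neutral", ss.SelectionModelSpec.neutral()),
]:
    ds = ss.generate_locus_dataset(
        model, mut, schedule, pool, seed=42, scale_factor=20, locus_id="demo"
    )
    summ = ss.locus_summary(ds)
    print(f"{label}:")
    print(f"  M_AS = {summ.M_AS:.2f}   V_AS = {summ.V_AS:.3f}")
    het = ", ".join(
        f"{p}={h:.2f}" for p, h in sorted(summ.per_population_heterozygosity.items())
    )
    print(f"  observed heterozygosity: {het}")
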