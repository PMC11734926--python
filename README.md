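# strsel — inference of natural selection on microsatellites

Microsatellites (short tandem repeats, STRs) are multiallelic, highly
mutable variants whose alleles are repeat counts. Whether and how natural
selection shapes their allele-frequency distributions is hard to assess
with SNP-oriented machinery: a locus with *n* alleles has *n(n+1)/2*
diploid genotypes, each potentially with its own fitness. `strsel` is a
library for researchers who want to ask, for a population sample of STR
genotypes: *is this locus evolving neutrally, and if not, under what kind
of fitness landscape, how strongly, and with what optimal allele size?*

## The models and the method

Five evolutionary models are compared. Under neutrality all genotypes
have relative fitness 1. The four selection models are parameterized by a
key allele size α and a selection strength s, with marginal allelic
fitness

* single optimum: `w(a) = exp(-s (a - α)²)`
* periodic optima: `w(a) = exp(-s · min(a - α⌊a/α⌋, α⌈a/α⌉ - a))`
  (every multiple of α is an optimum)

and genotype fitness either the mean (additive: ASO, APO) or the maximum
(dominant: DSO, DPO) of the two allelic fitnesses.

Inference is simulation-based (ABC with random forests):

1. A forward-in-time Wright–Fisher simulator evolves each locus through an
   eight-population human demographic history (Ne = 10,000, out-of-Africa
   style splits with founder events, linear regrowth), with viability
   selection and allele-size-dependent stepwise mutation
   (`μ_di(a) = (0.08 + 0.002a + 0.0002a²)/1000` for dinucleotides of size
   a ≥ 8). Starting allele-frequency distributions come from a stepwise
   mutation coalescent with θ ~ U[0.04, 40].
2. Each simulation is summarized as 408 features: per population, the
   frequencies of allele sizes 1–50 plus observed heterozygosity.
3. A random-forest classifier trained on such a reference table returns
   posterior model probabilities (tree vote fractions) for a query locus;
   out-of-bag predictions give unbiased error estimates. Regression
   forests with leaf-co-membership weighting estimate s with a 95%
   credible interval; a classification forest over integer α values
   estimates the key allele size.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import strsel as ss

pool = ss.build_afd_pool(ss.AFDPoolConfig(pool_size=50, n_haplotypes=200, seed=1))
schedule = ss.default_schedule()
model = ss.SelectionModelSpec(kind="ASO", s=0.015, alpha=9)

ds = ss.generate_locus_dataset(
    model, ss.MutationSpec.for_motif(2), schedule, pool,
    seed=42, scale_factor=20, locus_id="demo",
)
summ = ss.locus_summary(ds)
print(summ.M_AS, summ.V_AS)
```

Running `python examples/simulate_locus.py` (which does the above for a
selected and a neutral locus) prints:

```
ASO s=0.015 alpha=9:
  M_AS = 8.12   V_AS = 5.362
  observed heterozygosity: CEU=0.04, CHB=0.00, FIN=0.03, GIH=0.00, ...
neutral:
  M_AS = 21.95   V_AS = 30.762
  observed heterozygosity: CEU=0.64, CHB=0.70, FIN=0.60, GIH=0.80, ...
```

Strong selection collapses observed heterozygosity toward zero and pulls
the sample mean toward the key allele size, while the neutral locus keeps
the diversity of its starting distribution — exactly the contrast the
random forests exploit (observed heterozygosity is consistently the most
important feature). `examples/model_choice_pipeline.py` and
`examples/estimate_selection_strength.py` run the full train-and-classify
and parameter-estimation loops at desk scale;
`examples/min_s_search.py` shows the minimum-s analysis used for loci
sampled with zero variance. The `strsel` command exposes the same
pipeline for batch use (`strsel --help`).

All simulations accept a `scale_factor` that applies diffusion rescaling
(divide Ne and generation counts by c, multiply μ and s by c), preserving
N·μ and N·s so desk-scale runs reproduce full-scale behaviour in seconds.

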