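# Methods

`strsel` implements a simulation-based pipeline for inferring natural
selection on microsatellites (short tandem repeats, STRs) from population
samples of repeat-count genotypes. This note documents the models, the
default parameter values and why they hold, the numerical choices, and the
known limitations — particularly what the synthetic data generator does and
does not emulate.

## Selection models

An allele is its repeat count `a >= 1`. Five evolutionary models are
supported. Under neutrality every genotype has relative fitness 1. The four
selection models share two parameters: the key allele size `α` (the allele
of maximal marginal fitness) and the selection strength `s`.

Marginal fitness of allele `a`:

* single-optimum models (ASO, DSO): `w(a) = exp(-s (a - α)²)` — a Gaussian
  decline in squared distance from the optimum;
* periodic-optima models (APO, DPO):
  `w(a) = exp(-s · min(a - α·⌊a/α⌋, α·⌈a/α⌉ - a))` — an exponential decline
  in the *linear* distance to the nearest multiple of `α`, so every
  positive multiple of `α` is an optimum.

Genotype fitness is the mean of the two allelic marginal fitnesses under
the additive models (ASO, APO) and their maximum under the dominant models
(DSO, DPO). Dominance therefore creates fitness "ridges": every genotype
carrying at least one optimal allele has fitness 1.

Note a consequence of the periodic formula as written: for `a < α` the
floor term is `⌊a/α⌋ = 0`, so the distance to "0·α" competes with the
distance up to `α`, and alleles just above size 0 regain fitness. The
formula is implemented exactly as defined; users preferring optima only at
positive multiples can restrict `α ≤ a_min`.

Priors: `s ~ Uniform(0, 0.02]`, implemented as `Uniform[1e-6, 0.02]`
because the lower bound excludes exact neutrality; `α` uniform over the
integers `[2, 50]` (`α` is an allele size, hence integer).

## Mutation

Mutation probability per allele per generation depends on allele size.
For dinucleotides of size `a ≥ 8` the rate follows the empirical
polynomial `μ(a) = (0.08 + 0.002a + 0.0002a²)/1000` (≈1.1e-4 at a=8,
2.0e-4 at a=20). Alleles of size `< 8` mutate at a flat rate drawn
log-uniformly from `[1e-8, 1e-6]` per simulation — such short alleles are
essentially frozen on the simulated timescale.

Rate uncertainty is integrated over with a five-curve multiplicative
family `{0.25, 0.5, 1, 2, 4} ×` the baseline polynomial; one multiplier is
drawn uniformly per simulation. Motif sizes other than 2 scale the
dinucleotide baseline (default 0.5 for trinucleotides and longer motifs,
reflecting their lower and less certain rates); both the family and the
scale are configurable in `MutationSpec`.

A mutation changes allele size by a signed integer step: magnitude
geometric on {1, 2, ...} with success parameter 0.85 (single-repeat steps
dominate, occasional multi-step changes), direction +/- with equal
probability. The expansion/contraction symmetry is a deliberate
simplification — the empirical skew toward contractions at large sizes is
not modelled. Mutated sizes are clamped to `[1, max_allele]`
(default 120).

## Demography

Eight 1000 Genomes populations (CEU, CHB, FIN, GIH, LWK, MXL, TSI, YRI)
descend from a universal common ancestor (UCA) at equilibrium size
`Ne = 10,000` through a fixed binary split tree:
UCA→(YRI, NWACA), NWACA→(LWK, NACA), NACA→(MCA, EGCA), MCA→(MXL, CHB),
EGCA→(GIH, ECA), ECA→(FIN, WECA), WECA→(CEU, TSI). Out-of-Africa-style
events are peripatric (0.99/0.01 founding proportions); interior
bifurcations halve the parent; CEU and TSI each begin at 0.01 of WECA
because they are not truly sister populations. Descendants grow linearly,
+100 individuals per generation, until they reach `Ne`; there is no
migration. The UCA burn-in lasts 2,000 generations and the post-split
epoch 4,750 generations.

The exact split generations within the post-split epoch are not uniquely
determined by the published description; the bundled defaults (0, 1500,
2500, 3250, 3250, 3750, 4000) respect the split ordering and spacing and
are config-driven, so any alternative schedule can be supplied as YAML.

## Forward simulation

Each simulation draws a starting allele-frequency distribution (AFD) from
a pre-built pool; initializes the UCA with 10,000 diploids at
Hardy-Weinberg equilibrium; evolves it neutrally through burn-in; then per
generation and per population applies (i) viability selection — each
individual survives with probability equal to its genotype fitness, (ii)
random mating — parent pairs drawn with replacement from survivors
(self-pairing allowed by default, configurable), (iii) transmission of one
uniformly chosen allele per parent, and (iv) stepwise mutation of each
transmitted allele. Splits randomly partition a parent population into its
two descendants without replacement. If viability removes every
individual (possible when all genotypes are far from an optimum), the two
fittest individuals are retained as parents rather than aborting — the
choice matters only in the first generations after `α` is drawn far from
the standing distribution.

At the end, the eight leaf populations are sampled at the study sizes
(25, 27, 30, 25, 25, 18, 25, 25; 200 diploids total) and summarized as 408
features: per population, the frequencies of allele sizes 1–50 (computed
over all sampled alleles, so alleles above 50 count in the denominator but
have no bin) plus observed heterozygosity.

### Starting AFD pool

AFDs come from a single-population Kingman coalescent under the stepwise
mutation model: `θ = 4Ne·μ ~ Uniform[0.04, 40]` controls dispersion and an
integer ancestral allele size (default range `[5, 30]`) controls location;
mutations are Poisson on branches at rate θ/2 per lineage per coalescent
time unit, each a ±1 step clamped at size 1 (clamping is applied to node
values in topological order, a negligible approximation to per-event
clamping away from the boundary). The generator is validated against the
Ohta–Kimura equilibrium homozygosity `1/√(1+2θ)` and cross-checked against
msprime's stepwise mutation model at matched θ. The full-scale pool holds
20,000 AFDs of 1,000 haplotypes; desk-scale runs default to ~1,000 AFDs of
200 haplotypes, which preserves the θ and ancestral-size coverage with
coarser frequency granularity.

### Diffusion rescaling

A scale factor `c` divides `Ne` and all generation counts by `c` and
multiplies `μ` and `s` by `c`, preserving `N·μ` and `N·s` (the linear
growth rule `N(t) = N0 + 100t` maps onto itself). Sample sizes and
starting AFDs are unchanged. Scaled runs reproduce full-scale stochastic
behaviour except for features tied to the *absolute* mutation rate — most
visibly, the per-sample probability that a fresh mutation appears among
the 400 sampled alleles grows with `c·μ`, which inflates the rare-variant
floor of scaled samples. Default desk scale is `c = 20` (Ne 500, 100 + 238
generations).

## Reference tables and ABC-RF

A reference table pairs each simulation's 408 features with its generating
model label and parameters. Models are drawn uniformly (probability 0.2
each), `(s, α)` from their priors, and the mutation-curve multiplier and
small-allele rate are redrawn per simulation. Rows are generated on
independent, deterministic substreams of a single seed, so table builds
are reproducible, resumable from a partial file, and independent of
chunking. Full-scale tables hold 500,000 rows (documented, not exercised);
desk-scale method-performance checks use ≥5,000 rows at `c = 20`, and
single-model estimation tables ~100,000 rows at full scale.

Model choice trains a random-forest classifier (Gini criterion, bootstrap
per tree) with the tuned hyperparameters ntree=200, minobs=15 (minimum
observations to split), nfeat=20 features per split; a five-fold
cross-validated grid search over ntree ∈ {100,200,500},
nfeat ∈ {10,20,30,50}, minobs ∈ {5,15,50} is provided. A locus's
posterior probability for each model is its tree vote fraction; the OOB
confusion matrix supplies neutral→selection and selection→neutral error
rates and five-way accuracy without extra simulation. Variable importance
is mean Gini decrease; in practice the eight observed-heterozygosity
features dominate the ranking — overall polymorphism level is the primary
signal separating selection from neutrality.

Selection strength `s` is estimated with a regression forest: each
training row is weighted by the average frequency with which it shares a
terminal leaf with the query across trees; the posterior point estimate is
the weighted mean and the 95% interval the weighted 2.5%/97.5% quantiles.
This quantile interval is reported where a highest-posterior-density
interval would otherwise be quoted; for the unimodal posteriors seen in
practice the two nearly coincide. The key allele size `α` is treated as a
categorical label (classes 2–50) and estimated with a classification
forest whose vote fractions form the posterior; ties go to the smallest
α. Random forests are provided by scikit-learn; the leaf-weighting,
vote-fraction posteriors and OOB accounting are implemented here.

## Minimum-s search for invariant loci

For a locus sampled with zero variance in allele size, `s` is not
identifiable — any sufficiently strong selection erases all variation.
The reportable quantity is the minimum `s` that *maintains* invariance:
replicate simulations start monomorphic at the key allele `α` and a
candidate `s` passes when ≥95% of replicates (configurable) yield zero
variance across all 400 sampled alleles. Candidates are searched in
ascending order with early abandonment once enough failures accrue.

For small `α` (≤7) the mutation rate is ≤1e-6 and the smallest candidate
passes. For `α ≥ 8` the polynomial rate applies (≥1.1e-4), and
mutation–selection balance keeps non-key alleles at frequency ≈2μ/s, so
zero sampled variance in 400 alleles requires `s` far above the prior
range; the search then reports "above range" with the largest tested `s`
as a lower bound. This is the quantitative reading of empirical
invariant loci at `α = 8` being annotated with a bound (">0.003") rather
than a point estimate.

## Synthetic genotype datasets

`generate_locus_dataset` wraps one full simulation in the empirical data
shape: 200 individuals across the eight populations, tab-separated
records with integer repeat-count alleles normalized to
`allele1 ≤ allele2`, missing genotypes as `.`, and the generating truth
`(kind, s, α, seed)` attached. `locus_summary` reports global mean and
variance of allele size (M_AS, V_AS; population-variance convention,
denominator n, alleles pooled across populations with equal weight per
allele) plus per-population means and observed heterozygosities. An
optional heterozygote-dropout operator (off by default) emulates the
allelic dropout typical of short-read STR calls for robustness
experiments.

What the generator emulates: realistic allele-frequency distributions
shaped by the demographic history, size-dependent mutation, and any of the
five selection models, with exact ground truth. What it does not emulate:
genotyping error and allelic dropout (unless enabled), repeat
imperfections, contraction-biased mutation at large sizes, linked
selection, gene flow, and — importantly — the long-run equilibrium
coupling between mean allele size and variance. Because the starting-AFD
dispersion θ is drawn independently of the ancestral allele size, batch
V_AS across θ-spanning neutral loci is dominated by the starting state
rather than by size-dependent mutation; the positive V_AS–M_AS trend seen
in real intergenic dinucleotides emerges in synthetic batches only when θ
is held fixed so the forward process drives the differences (this is how
the packaged trend test is constructed). Passing tests therefore validate
the machinery and the selection signal, not distributional realism of any
single real locus.

## Numerical and design choices

* All randomness flows from a single integer seed through
  `numpy.random.default_rng([seed, stream, index])` substreams; identical
  seeds give byte-identical tables, datasets and forests.
* Populations are stored as `(2, N)` int16 arrays; fitness and mutation
  rates are precomputed dense lookup tables (float32 in the hot loop —
  rates below ~6e-8 are quantized by the float32 uniform, irrelevant at
  less than one expected event per simulation).
* When selfing is allowed (default), drawing a parent and then one of its
  two alleles is realized as a single uniform draw over all 2N
  chromosomes.
* Genotype fitness tie-breaks: the model-choice argmax resolves ties in
  the fixed order NEUTRAL < ASO < DSO < APO < DPO; the α argmax prefers
  the smallest label.
* Desk-scale problem sizes used by the packaged evaluation: AFD pool
  1,000 × 200 haplotypes; reference table 5,000 rows at scale 20 for the
  five-way classifier; ~1,000-row single-model subsets for estimation
  checks; these sizes were chosen once as the smallest at which the
  method-performance quantities stabilize.

## Known limitations

* Split times and most founding proportions are plausible defaults, not
  inferred quantities; conclusions sensitive to the internal branching
  order should treat them as configurable assumptions.
* Trinucleotide and longer-motif mutation curves are scaled dinucleotide
  curves, not independent empirical estimates.
* Scaled-down OOB error rates track, but do not exactly equal, full-scale
  rates; five-way accuracy in particular increases with reference-table
  size.
* The advanced population-specific selection models (different `s`, `α`
  in African vs non-African populations) and secondary-regression
  posterior corrections are out of scope.
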