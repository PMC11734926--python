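"""Minimum selection strength that maintains an invariant locus.

For a locus observed with zero variance in allele size, s is not
identifiable from the data: any sufficiently strong selection erases all
variation.  The reportable quantity is the minimum s at which replicate
simulations (starting monomorphic at the key allele) consistently yield
zero sampled variance.  For a dinucleotide with alpha = 8 the mutation
rate at the key allele is high enough (~1.1e-4 per generation) that
mutation-selection balance keeps reintroducing variants; the search then
reports that the minimum lies above the explored prior range.
"""

import strsel as ss

schedule = ss.default_schedule()
result = ss.min_s_for_invariance(
    ss.ModelKind.ASO,
    alpha=8,
    mut=ss.MutationSpec.for_motif(2),
    schedule=schedule,
    n_reps=30,
    seed=5,
    scale_factor=20,
    s_grid=(0.001, 0.003, 0.01, 0.02),
)
print("zero-variance fraction per candidate s:")
for s, frac in sorted(result.fractions.items()):
    print(f"  s = {s:<7g} -> {frac:.2f}")
if result.above_range:
    print(f"minimum s is above the searched range (> {result.lower_bound})")
else:
    print(f"minimum s = {result.min_s}")
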