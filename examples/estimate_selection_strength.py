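"""Estimate s and alpha for a locus with the regression/classification forests.

Builds a single-model (ASO) reference table, trains the leaf-weighted
regression forest for the selection strength s and the classification
forest for the key allele size alpha, then queries a fresh simulation with
known truth.  The s posterior is reported as a point estimate with a 95%
credible interval (weighted 2.5%/97.5% quantiles); the alpha posterior is
the vote fraction of its argmax label.
"""

import numpy as np

import strsel as ss

SEED = 13
pool = ss.build_afd_pool(ss.AFDPoolConfig(pool_size=200, n_haplotypes=200, seed=SEED))
schedule = ss.default_schedule()

table = ss.build_reference_table(
    500, 2, schedule, pool, seed=SEED, scale_factor=20,
    kinds=[ss.ModelKind.ASO],
)
hp = ss.Hyperparams(ntree=200, nfeat=20, minobs=15)
s_forest = ss.SelectionStrengthForest(table, hp, seed=SEED)
a_forest = ss.AlphaClassificationForest(table, hp, seed=SEED)

truth = ss.SelectionModelSpec(kind="ASO", s=0.012, alpha=11)
res = ss.run_simulation(
    ss.rescale_schedule(schedule, 20),
    ss.rescale_model(truth, 20),
    ss.rescale_mutation(ss.MutationSpec.for_motif(2), 20),
    pool,
    np.random.default_rng(SEED),
)
s_post = s_forest.posterior(res.features)
a_post = a_forest.posterior(res.features)
print(f"true s = {truth.s}, true alpha = {truth.alpha}")
print(f"estimated s = {s_post.point:.4f}  95% CI ({s_post.interval[0]:.4f}, {s_post.interval[1]:.4f})")
print(f"estimated alpha = {a_post.point:.0f}  posterior {a_post.point_probability:.3f}")
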