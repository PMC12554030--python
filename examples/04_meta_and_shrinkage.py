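"""External meta-analysis and continuous-shrinkage posterior weights.

Emulates a multi-cohort univariate association meta-analysis, filters
genome-wide-significant hits, and feeds the marginal effects through the
gamma-gamma continuous-shrinkage Gibbs sampler with a block LD reference.
"""

import numpy as np
import pandas as pd

from memoscore.csprs import (CsConfig, auto_phi_summary, build_ld_reference,
                             sample_posterior_effects)
from memoscore.sumstats import meta_fixed, top_hits
from memoscore.synthcohort import (SimConfig, block_partition, simulate_cohort,
                                   simulate_external_sumstats)

cfg = SimConfig(n_samples=600, n_variants=600, n_blocks=12,
                n_causal_variants=8, h2_genetic=0.3,
                n_external_cohorts=10, external_n_per_cohort=2000, seed=5)
panel, cohort, truth = simulate_cohort(cfg)

tables = simulate_external_sumstats(cfg, truth)
meta = meta_fixed(tables)
hits = top_hits(meta, 5e-8)
print(f"meta-analysis: {len(tables)} cohorts, total N = {meta['n'].max()}, "
      f"{len(hits)} variants at p < 5e-8")

ld = build_ld_reference(panel, block_partition(panel))
weights, chain = sample_posterior_effects(
    meta, ld, CsConfig(phi="auto", n_iter=600, n_burnin=300, thin=2, seed=1),
    return_chain=True)

true = pd.Series(truth.variant_effects, index=panel.variant_ids)
w = weights.set_index("feature_id")["weight"]
marg = meta.set_index("variant_id")["beta"]
common = w.index
print(f"corr(truth, posterior means) = {np.corrcoef(true[common], w[common])[0,1]:.3f}")
print(f"corr(truth, raw marginals)   = {np.corrcoef(true[common], marg[common])[0,1]:.3f}")
phi = auto_phi_summary(chain)
print(f"global shrinkage phi: median {phi['median']:.3g}, "
      f"90% CI ({phi['ci90'][0]:.3g}, {phi['ci90'][1]:.3g})")
# Shrinking null marginals toward zero while keeping true signals is what
# lifts the posterior correlation above the raw-marginal one.
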