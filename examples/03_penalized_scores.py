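"""Train the genome-wide and metabolome-wide penalized scores.

The genome-wide LASSO is tuned on a single training/validation split, the
metabolome-wide LASSO by 10-fold cross-validation; both adjust for CAIDE
and age without shrinking them, and export per-unit weight tables.
"""

import pandas as pd

from memoscore.penalized import export_weights, make_problem, tune_by_cv, tune_by_split
from memoscore.synthcohort import SimConfig, metabolite_columns, simulate_cohort

cfg = SimConfig(n_samples=900, n_variants=800, n_blocks=16,
                n_causal_variants=8, h2_genetic=0.3, var_metabolic=0.1,
                seed=3)
panel, cohort, truth = simulate_cohort(cfg)
covs = cohort[["caide", "age_at_test"]]

prob_g = make_problem(pd.DataFrame(panel.dosages, columns=panel.variant_ids),
                      covs, cohort["em_score"])
fit_g = tune_by_split(prob_g, train_frac=0.8, seed=0)
w_prs = export_weights(fit_g, panel.variants, "LASSO-PRS")
hit = set(w_prs.feature_id) & set(truth.causal_variant_ids)
print(f"genome-wide LASSO: lambda={fit_g.lam:.4g}, selected "
      f"{fit_g.n_selected} variants ({len(hit)}/{len(truth.causal_variant_ids)}"
      " true causals among them)")

prob_m = make_problem(cohort[metabolite_columns(cohort)], covs,
                      cohort["em_score"])
fit_m = tune_by_cv(prob_m, k=10, seed=0)
w_mrs = export_weights(fit_m, None, "MRS")
hit_m = set(w_mrs.feature_id) & set(truth.causal_metabolite_ids)
print(f"metabolome-wide LASSO: lambda={fit_m.lam:.4g}, selected "
      f"{fit_m.n_selected} metabolites ({len(hit_m)}/"
      f"{len(truth.causal_metabolite_ids)} true causals among them)")
print(w_mrs.head().to_string(index=False))
# Weights are on the raw per-allele / per-metabolite-unit scale, ready for
# weighted-sum scoring in an independent sample.
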