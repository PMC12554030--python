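"""Reproducible synthetic-study experiments.

These drivers run the pipeline's core claims on freshly generated synthetic
cohorts at the generator's study-scale conditions (train n=897 / test n=104,
sparse genetic architecture, external meta-analysis of many ~1.3k-sample
cohorts) and return the quantities of scientific interest: how well each
score recovers the planted signal, and whether the layered FDR evaluation
reproduces the expected significance pattern.  Both the test suite and
``scripts/acceptance.py`` call these, so the reported numbers always come
from end-to-end computation.
"""

from __future__ import annotations

import dataclasses
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .csprs import CsConfig, build_ld_reference, sample_posterior_effects
from .dataio import read_table
from .penalized import export_weights, make_problem, tune_by_split
from .pipeline import load_config, run_study
from .scoring import score_genetic
from .sumstats import meta_fixed
from .synthcohort import (SimConfig, block_partition, simulate_cohort,
                          simulate_external_sumstats)


def recovery_run(seed: int, sim_overrides: dict | None = None,
                 test_n: int = 104, cs_iter: int = 300) -> dict:
    """One replicate of the signal-recovery experiment at generator defaults.

    Simulates a cohort (defaults: 1001 samples, 5000 variants in 50 LD
    blocks, h^2 = 0.3 over 10 causal variants), trains the genome-wide
    penalized score on 897 samples, scores the 104 held-out samples, and
    separately runs the emulated external meta-analysis (~20 cohorts,
    ~30k samples) through the continuous-shrinkage sampler.

    Returns correlations of (a) the held-out polygenic score with the true
    additive genetic value, and (b) posterior-mean vs raw marginal effects
    with the true per-allele effects.
    """
    cfg = SimConfig(**{**(sim_overrides or {}), "seed": int(seed)})
    panel, cohort, truth = simulate_cohort(cfg)

    rng = np.random.default_rng([7, int(seed)])
    perm = rng.permutation(cfg.n_samples)
    test_idx, train_idx = np.sort(perm[:test_n]), np.sort(perm[test_n:])
    train_panel = panel.subset_samples(train_idx)
    test_panel = panel.subset_samples(test_idx)
    train_cohort = cohort.iloc[train_idx]

    prob = make_problem(
        pd.DataFrame(train_panel.dosages, columns=train_panel.variant_ids),
        train_cohort[["caide", "age_at_test"]],
        train_cohort["em_score"])
    fit = tune_by_split(prob, seed=int(seed))
    weights = export_weights(fit, train_panel.variants, "LASSO-PRS")

    g_true = test_panel.dosages @ truth.variant_effects
    if len(weights) and g_true.std() > 0:
        prs, _ = score_genetic(weights, test_panel)
        corr_lasso = float(np.corrcoef(prs, g_true)[0, 1]) if prs.std() > 0 else 0.0
    else:
        corr_lasso = 0.0

    ext = simulate_external_sumstats(cfg, truth)
    meta = meta_fixed(ext)
    ld = build_ld_reference(train_panel, block_partition(train_panel))
    cs_cfg = CsConfig(n_iter=cs_iter, n_burnin=cs_iter // 2, thin=2,
                      seed=int(seed))
    w_cs = sample_posterior_effects(meta, ld, cs_cfg).set_index("feature_id")
    meta_idx = meta.set_index("variant_id")
    order = [v for v in panel.variant_ids if v in w_cs.index]
    post = w_cs.loc[order, "weight"].to_numpy()
    marg = meta_idx.loc[order, "beta"].to_numpy()
    true = pd.Series(truth.variant_effects,
                     index=panel.variant_ids)[order].to_numpy()
    return {
        "corr_lasso": corr_lasso,
        "corr_posterior": float(np.corrcoef(post, true)[0, 1]),
        "corr_marginal": float(np.corrcoef(marg, true)[0, 1]),
        "n_selected_lasso": int(fit.n_selected),
    }


def signal_vs_null_run(seed: int, n_variants: int = 2000, n_blocks: int = 20,
                       n_external_cohorts: int = 10,
                       external_n_per_cohort: int = 1000,
                       cs_iter: int = 300) -> dict:
    """One replicate of the conclusion-pattern experiment.

    Runs the full study (at a reduced variant panel for tractability) with a
    planted genetic signal (h^2 = 0.3) and *null* metabolome and CAIDE
    layers, test n = 104.  Returns the within-layer FDR-adjusted p-values of
    each risk-score family across all models and both test datasets, plus
    the incremental-R^2 table.
    """
    cfg = load_config()
    cfg["seed"] = int(seed)
    cfg["synthetic"] = {
        "n_samples": 1001, "n_variants": n_variants, "n_blocks": n_blocks,
        "n_causal_variants": 10, "h2_genetic": 0.3,
        "var_metabolic": 0.0, "var_caide": 0.0,
        "n_external_cohorts": n_external_cohorts,
        "external_n_per_cohort": external_n_per_cohort,
    }
    cfg["test_n"] = 104
    cfg["csprs"] = {"phi": "auto", "n_iter": cs_iter,
                    "n_burnin": cs_iter // 2, "thin": 2}
    cfg["children"] = []
    with tempfile.TemporaryDirectory() as td:
        manifest = run_study(config=cfg, out_dir=td)
        fdr = read_table(Path(td) / "fdr_within_layer.tsv")
        comparisons = read_table(Path(td) / "comparisons.tsv")
    out = {"manifest": manifest, "comparisons": comparisons}
    for term in ("caide", "mrs", "lasso_prs", "gwama_prs"):
        out[term] = fdr.loc[fdr["term"] == term, "p_adj"].tolist()
    return out
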