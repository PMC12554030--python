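"""End-to-end orchestration of the multiomics prediction study.

:func:`run_study` executes, on synthetic (or user-supplied) data, the full
sequence: cohort simulation -> CAIDE score -> held-out test split ->
genome-wide and metabolome-wide penalized regressions on the non-test
samples -> emulated external meta-analysis -> continuous-shrinkage posterior
weights -> score construction and within-test-sample standardization ->
the nested-model grid with layered FDR control -> stroke-exclusion
sensitivity rerun -> optional children-cohort transfer evaluation.

A single top-level seed deterministically derives all stage seeds, and every
stage output is written as TSV/JSON next to a manifest, so reruns with the
same configuration are byte-identical and any stage can be reproduced in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caide import add_caide
from .csprs import CsConfig, build_ld_reference, sample_posterior_effects
from .dataio import GenotypePanel, harmonize_alleles, write_genotypes, write_table
from .evaluate import fdr_layers, run_grid, sensitivity_exclude
from .penalized import (LassoFit, export_weights, fit_lasso_path, make_problem,
                        tune_by_cv, tune_by_split)
from .scoring import score_genetic, score_metabolic, standardize_scores
from .sumstats import meta_fixed, top_hits
from .synthcohort import (SimConfig, block_partition, metabolite_columns,
                          simulate_cohort, simulate_external_sumstats)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "test_n": 104,
    "synthetic": {},            # SimConfig overrides
    "lasso": {"train_frac": 0.8, "k": 10, "grid_size": 100,
              "lambda_min_ratio": 0.001, "tol": 1e-7},
    "csprs": {"phi": "auto", "n_iter": 1000, "n_burnin": 500, "thin": 5},
    "ancestry_pcs": 3,
    "significance_threshold": 5e-8,
    "children": [
        {"name": "child_a", "n_samples": 309, "age_mean": 11.9, "overlap": 0.93},
        {"name": "child_b", "n_samples": 443, "age_mean": 8.6, "overlap": 0.945},
    ],
}


class ConfigError(ValueError):
    pass


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        for key, val in user.items():
            if key not in cfg:
                raise ConfigError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _stage_seeds(seed: int) -> dict:
    """Derive one deterministic 31-bit seed per stage from the top seed."""
    ss = np.random.SeedSequence(seed)
    names = ["sim", "split", "lasso_gwas", "lasso_mwas", "external",
             "csprs", "children"]
    vals = ss.generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(v) for v in vals)))


def _tuned_with_fallback(problem, tuner, **kw) -> LassoFit:
    """Run a tuning protocol; if the chosen model is empty, fall back to the
    best-loss lambda whose training-path fit selects at least one feature.

    The evaluation grid needs a non-degenerate score column, so a selected
    set of size zero (possible under a null layer) is replaced by the
    smallest admissible model rather than a constant score.
    """
    fit = tuner(problem, **kw)
    if fit.n_selected > 0:
        return fit
    path = fit_lasso_path(problem)
    curve = fit.tuning_curve
    order = np.argsort(curve["loss"].to_numpy(), kind="stable")
    for idx in order:
        if path[idx].n_selected > 0:
            chosen = path[idx]
            chosen.tuning_curve = curve
            logger.info("tuning fallback: empty model at the loss minimum; "
                        "using lambda=%.4g (%d features)", chosen.lam,
                        chosen.n_selected)
            return chosen
    return fit  # genuinely nothing selectable anywhere on the path


def run_study(config_path=None, config: dict | None = None,
              out_dir="study_out") -> dict:
    """Run the whole study; returns the manifest dict (also written to disk)."""
    cfg = config if config is not None else load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))

    # --- stage 1: simulate cohort (CAIDE computed inside the generator)
    sim_cfg = SimConfig(**{**cfg["synthetic"], "seed": seeds["sim"]})
    panel, cohort, truth = simulate_cohort(sim_cfg)
    truth.to_json(out / "true_model.json")

    # ancestry PCs on the full panel
    from .dataio import compute_ancestry_pcs
    k_pc = int(cfg["ancestry_pcs"])
    pcs = compute_ancestry_pcs(panel, k=k_pc)
    pc_cols = [f"pc{i + 1}" for i in range(k_pc)]
    for i, c in enumerate(pc_cols):
        cohort[c] = pcs[:, i]

    # --- stage 2: held-out test split
    test_n = int(cfg["test_n"])
    if not 0 < test_n < sim_cfg.n_samples:
        raise ConfigError(f"test_n={test_n} incompatible with "
                          f"n_samples={sim_cfg.n_samples}")
    rng = np.random.default_rng(seeds["split"])
    perm = rng.permutation(sim_cfg.n_samples)
    test_idx, train_idx = np.sort(perm[:test_n]), np.sort(perm[test_n:])
    train_cohort = cohort.iloc[train_idx].reset_index(drop=True)
    test_cohort = cohort.iloc[test_idx].reset_index(drop=True)
    train_panel = panel.subset_samples(train_idx)
    test_panel = panel.subset_samples(test_idx)

    lp = cfg["lasso"]

    # --- stage 3a: genome-wide LASSO (covariates: CAIDE, age, ancestry PCs)
    gwas_cov = train_cohort[["caide", "age_at_test", *pc_cols]]
    prob_g = make_problem(
        pd.DataFrame(train_panel.dosages, columns=train_panel.variant_ids),
        gwas_cov, train_cohort["em_score"],
        grid_size=int(lp["grid_size"]),
        lambda_min_ratio=float(lp["lambda_min_ratio"]), tol=float(lp["tol"]))
    fit_g = _tuned_with_fallback(prob_g, tune_by_split,
                                 train_frac=float(lp["train_frac"]),
                                 seed=seeds["lasso_gwas"])
    w_lasso = export_weights(fit_g, train_panel.variants, "LASSO-PRS")
    write_table(w_lasso, out / "weights_lasso_prs.tsv")

    # --- stage 3b: metabolome-wide LASSO (covariates: CAIDE, age, interval)
    met_cols = metabolite_columns(cohort)
    mwas_cov = train_cohort[["caide", "age_at_test", "draw_interval"]]
    prob_m = make_problem(train_cohort[met_cols], mwas_cov,
                          train_cohort["em_score"],
                          grid_size=int(lp["grid_size"]),
                          lambda_min_ratio=float(lp["lambda_min_ratio"]),
                          tol=float(lp["tol"]))
    fit_m = _tuned_with_fallback(prob_m, tune_by_cv, k=int(lp["k"]),
                                 seed=seeds["lasso_mwas"])
    w_mrs = export_weights(fit_m, None, "MRS")
    write_table(w_mrs, out / "weights_mrs.tsv")

    # --- stage 4: external meta-analysis + continuous-shrinkage weights
    ext_cfg = dataclasses.replace(sim_cfg, seed=seeds["external"])
    tables = simulate_external_sumstats(ext_cfg, truth)
    meta = meta_fixed(tables)
    write_table(meta, out / "meta_analysis.tsv")
    hits = top_hits(meta, float(cfg["significance_threshold"]))
    write_table(hits, out / "top_hits.tsv")

    ld = build_ld_reference(train_panel, block_partition(train_panel))
    cs_cfg = CsConfig(**{**cfg["csprs"], "seed": seeds["csprs"]})
    w_gwama = sample_posterior_effects(meta, ld, cs_cfg)
    write_table(w_gwama, out / "weights_gwama_prs.tsv")

    # --- stage 5: score + standardize in the test sample
    coverage = {}
    test_scored = test_cohort.copy()
    for name, wt in (("lasso_prs", w_lasso), ("gwama_prs", w_gwama)):
        if len(wt):
            aligned, report = harmonize_alleles(wt, test_panel)
            sc, cov = score_genetic(aligned, test_panel)
            coverage[name] = {**report, **cov}
        else:
            sc = np.zeros(test_panel.n_samples)
            coverage[name] = {"n_weights": 0, "coverage": 0.0}
        test_scored[f"score_{name}"] = _safe_standardize(sc)
    mrs_raw = score_metabolic(w_mrs, test_scored[met_cols])
    test_scored["score_mrs"] = _safe_standardize(mrs_raw)

    # --- stage 6: evaluation grid, two test datasets, layered FDR
    background = ["age_at_test", "draw_interval", *pc_cols]
    datasets = {"test": test_scored,
                "test_nostroke": sensitivity_exclude(test_scored)}
    all_fits, all_cmp, all_records = {}, [], []
    for ds_name, ds in datasets.items():
        fits, cmps, records = run_grid(ds, background, ds_name)
        all_fits[ds_name] = fits
        all_cmp.extend((ds_name, c) for c in cmps)
        all_records.append(records)
    records = pd.concat(all_records, ignore_index=True)
    fdr_within = fdr_layers(records, "within_layer")
    fdr_per_prs = fdr_layers(records, "per_prs")
    write_table(fdr_within, out / "fdr_within_layer.tsv")
    write_table(fdr_per_prs, out / "fdr_per_prs.tsv")

    fits_rows = []
    for ds_name, fits in all_fits.items():
        for label, f in fits.items():
            fits_rows.append((ds_name, label, f.n, f.r2, f.adj_r2, f.aic, f.bic))
    fits_df = pd.DataFrame(fits_rows, columns=["dataset", "model", "n", "r2",
                                               "adj_r2", "aic", "bic"])
    write_table(fits_df.sort_values(["dataset", "model"]).reset_index(drop=True),
                out / "model_fits.tsv")
    cmp_df = pd.DataFrame(
        [(ds, c.baseline_label, c.extended_label, c.delta_r2_pp, c.delta_adj_r2,
          c.delta_aic, c.delta_bic, json.dumps(c.added_terms, sort_keys=True))
         for ds, c in all_cmp],
        columns=["dataset", "baseline", "extended", "delta_r2_pp",
                 "delta_adj_r2", "delta_aic", "delta_bic", "added_term_p"])
    write_table(cmp_df.sort_values(["dataset", "baseline", "extended"])
                .reset_index(drop=True), out / "comparisons.tsv")

    # --- stage 7: children transfer cohorts
    children_fdr = None
    child_records = []
    for child in cfg.get("children") or []:
        rec = _child_transfer(child, truth, sim_cfg, seeds["children"],
                              {"lasso_prs": w_lasso, "gwama_prs": w_gwama},
                              coverage)
        child_records.append(rec)
    if child_records:
        child_df = pd.concat(child_records, ignore_index=True)
        children_fdr = fdr_layers(child_df, "within_layer")
        write_table(children_fdr, out / "fdr_children.tsv")

    manifest = {
        "version": __version__,
        "seed": int(cfg["seed"]),
        "stage_seeds": seeds,
        "sim_config": dataclasses.asdict(sim_cfg),
        "n_train": int(len(train_idx)), "n_test": int(len(test_idx)),
        "n_test_nostroke": int(len(datasets["test_nostroke"])),
        "lasso_prs_n_variants": int(len(w_lasso)),
        "mrs_n_metabolites": int(len(w_mrs)),
        "gwama_prs_n_variants": int(len(w_gwama)),
        "n_top_hits": int(len(hits)),
        "coverage": coverage,
        "model_specs": sorted(all_fits["test"].keys()),
        "fdr_schemes": ["within_layer", "per_prs"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def _safe_standardize(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.std(ddof=1) == 0:
        logger.warning("degenerate (constant) score left unstandardized")
        return scores - scores.mean()
    return standardize_scores(scores)


def _child_transfer(child: dict, truth, sim_cfg: SimConfig, seed: int,
                    weight_tables: dict, coverage: dict) -> pd.DataFrame:
    """Score adult-derived PRSs in a simulated child cohort and test them
    against the child covariate-only model.

    By default the child outcome carries no genetic signal, emulating a
    transfer failure; the panel drops a configurable fraction of each weight
    table's variants to mirror incomplete imputation overlap.
    """
    from .evaluate import ModelSpec, fit_model
    from .synthcohort import _draw_dosages, _rng

    name = child["name"]
    n = int(child["n_samples"])
    overlap = float(child.get("overlap", 0.93))
    h2_child = float(child.get("h2_genetic", 0.0))
    import zlib
    rng = np.random.default_rng([seed, zlib.crc32(name.encode()) % 2**31])

    variants = truth.variants
    dos = _draw_dosages(variants, n, sim_cfg.ld_rho, rng)
    panel = GenotypePanel(
        np.array([f"{name}_{i}" for i in range(n)], dtype=object),
        variants.copy(), dos)

    age = rng.normal(float(child.get("age_mean", 10.0)), 0.4, n)
    sex = np.where(rng.random(n) < 0.5, 1.0, 0.0)
    m_edu = np.maximum(rng.normal(13, 3, n), 6)
    g = dos @ np.asarray(truth.variant_effects)
    if h2_child > 0 and g.std() > 0:
        g = (g - g.mean()) / g.std() * np.sqrt(h2_child)
    else:
        g = np.zeros(n)
    y = g + 0.1 * (m_edu - m_edu.mean()) + rng.normal(0, np.sqrt(1 - h2_child), n)
    cohort = pd.DataFrame({"sample_id": panel.sample_ids, "em_score": y,
                           "age_at_test": age, "sex_num": sex,
                           "maternal_education": m_edu})

    rows = []
    for term, wt in weight_tables.items():
        if not len(wt):
            continue
        keep = rng.random(len(wt)) < overlap
        sub_panel = _drop_weight_variants(panel, wt, keep)
        aligned, report = harmonize_alleles(wt, sub_panel)
        sc, cov = score_genetic(aligned, sub_panel)
        coverage[f"{name}_{term}"] = {**report, **cov}
        cohort[f"score_{term}"] = _safe_standardize(sc)
        spec = ModelSpec(label=f"{name}+{term}",
                         background=("age_at_test", "sex_num",
                                     "maternal_education"),
                         risk_terms=(term,))
        fit = fit_model(spec, cohort)
        rows.append((term, spec.label, name, fit.term_p(term)))
    return pd.DataFrame(rows, columns=["term", "model", "dataset", "p"])


def _drop_weight_variants(panel: GenotypePanel, weights: pd.DataFrame,
                          keep_mask: np.ndarray) -> GenotypePanel:
    dropped = set(weights.loc[~keep_mask, "feature_id"])
    keep_ids = [v for v in panel.variant_ids if v not in dropped]
    return panel.subset_variants(keep_ids)


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int, out_dir) -> dict:
    """Small deterministic fixture files exercising every reader.

    50 samples x 60 variants, 10 metabolites, toy summary stats, and a toy
    weight/panel pair hitting one allele flip, one strand-ambiguous drop and
    one missing variant.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_samples=50, n_variants=60, n_blocks=6, n_causal_variants=5,
                    n_metabolites=10, n_causal_metabolites=3, metab_block_size=5,
                    n_external_cohorts=2, external_n_per_cohort=100, seed=seed)
    panel, cohort, truth = simulate_cohort(cfg)
    write_genotypes(panel, out / "panel.tsv", dialect="tsv")
    write_table(cohort, out / "cohort.tsv")
    truth.to_json(out / "true_model.json")
    tables = simulate_external_sumstats(cfg, truth)
    for i, t in enumerate(tables):
        write_table(t, out / f"sumstats_cohort{i}.tsv")

    # toy weight/panel pair: flip, ambiguous, missing
    v = panel.variants.iloc[:3].copy()
    v.loc[v.index[1], ["effect_allele", "other_allele"]] = ["A", "T"]  # ambiguous
    toy_panel = GenotypePanel(panel.sample_ids[:4], v, panel.dosages[:4, :3])
    write_genotypes(toy_panel, out / "toy_panel.tsv", dialect="tsv")
    wt = pd.DataFrame({
        "feature_id": [v.iloc[0]["variant_id"], v.iloc[1]["variant_id"],
                       v.iloc[2]["variant_id"], "v_absent"],
        "effect_allele": [str(v.iloc[0]["other_allele"]), "A",
                          str(v.iloc[2]["effect_allele"]), "A"],
        "weight": [0.5, 0.25, -0.4, 1.0],
        "source_label": "LASSO-PRS",
    })
    write_table(wt, out / "toy_weights.tsv")
    return {"files": sorted(p.name for p in out.iterdir())}
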