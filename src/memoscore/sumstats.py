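"""Univariate per-variant association, fixed-effect meta-analysis, filtering.

:func:`run_gwas` regresses the memory outcome on each variant's dosage plus a
common covariate set.  With a shared covariate block the per-variant ordinary
least squares fit reduces, by the Frisch-Waugh-Lovell theorem, to a simple
regression of covariate-residualized outcome on covariate-residualized
dosage, which vectorizes over the whole panel; betas, standard errors and
t-based p-values are identical to fitting each full model separately.

:func:`meta_fixed` pools per-cohort tables with inverse-variance weights
(w_i = 1/se_i^2), the fixed-effect convention of the standard meta-analysis
tools; Cochran's Q and I^2 are reported but not acted on.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GenotypePanel, SUMSTATS_COLUMNS, mean_impute, validate_sumstats

logger = logging.getLogger(__name__)

META_COLUMNS = SUMSTATS_COLUMNS + ["z", "q", "i2", "n_cohorts"]


def run_gwas(panel: GenotypePanel, cohort: pd.DataFrame,
             covariates: list[str] | None = None,
             outcome: str = "em_score") -> pd.DataFrame:
    """Per-variant OLS of the outcome on dosage + covariates + intercept.

    Returns a summary-stats table (variant_id, effect_allele, other_allele,
    beta, se, p, n).  Monomorphic variants are emitted with missing beta and
    logged.  Requires >= 10 samples; collinear covariates raise with the
    offending column names.
    """
    covariates = covariates or []
    cohort = cohort.set_index("sample_id").loc[list(panel.sample_ids)]
    y = cohort[outcome].to_numpy(float)
    n = len(y)
    if n < 10:
        raise ValueError(f"run_gwas needs >= 10 samples, got {n}")
    C = np.column_stack([np.ones(n)] + [cohort[c].to_numpy(float) for c in covariates])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        raise ValueError(f"collinear covariates among {['intercept'] + covariates}")
    k = C.shape[1]
    Q, _ = np.linalg.qr(C)
    yt = y - Q @ (Q.T @ y)
    G = panel.dosages
    if np.isnan(G).any():
        G = mean_impute(G)
    # residualize dosages with a single temporary (these matrices are large)
    Gt = np.dot(Q, Q.T @ G)
    np.subtract(G, Gt, out=Gt)

    gg = np.einsum("ij,ij->j", Gt, Gt)
    mono = np.ptp(G, axis=0) == 0
    if mono.any():
        logger.info("run_gwas: %d monomorphic variants flagged", int(mono.sum()))
    gg_safe = np.where(gg > 1e-12, gg, np.nan)
    beta = (yt @ Gt) / gg_safe
    dof = n - k - 1
    rss = (yt @ yt) - beta**2 * gg_safe
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
        p = 2 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)
    p = np.where(mono, np.nan, p)

    out = pd.DataFrame(
        {"variant_id": panel.variants["variant_id"],
         "effect_allele": panel.variants["effect_allele"],
         "other_allele": panel.variants["other_allele"],
         "beta": beta, "se": se, "p": p, "n": n}
    )
    return validate_sumstats(out)


def meta_fixed(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effect meta-analysis of summary-stat tables.

    Alleles are harmonized to the first table listing each variant (betas of
    cohorts reporting the swapped allele pair are negated); irreconcilable
    allele pairs are dropped with a log entry.  Variants present in only some
    cohorts are meta-analyzed over the cohorts that have them.
    """
    if not tables:
        raise ValueError("meta_fixed needs at least one table")
    for t in tables:
        validate_sumstats(t)
    ref: dict[str, tuple[str, str]] = {}
    acc: dict[str, list[tuple[float, float, float]]] = {}
    for t in tables:
        for row in t.itertuples(index=False):
            if not np.isfinite(row.beta):
                continue
            ea, oa = str(row.effect_allele).upper(), str(row.other_allele).upper()
            if row.variant_id not in ref:
                ref[row.variant_id] = (ea, oa)
                acc[row.variant_id] = []
            rea, roa = ref[row.variant_id]
            if (ea, oa) == (rea, roa):
                sign = 1.0
            elif (ea, oa) == (roa, rea):
                sign = -1.0
            else:
                logger.info("meta_fixed: dropping %s in one cohort "
                            "(irreconcilable alleles %s/%s vs %s/%s)",
                            row.variant_id, ea, oa, rea, roa)
                continue
            acc[row.variant_id].append((sign * row.beta, row.se, row.n))

    rows = []
    for vid, entries in acc.items():
        if not entries:
            continue
        b = np.array([e[0] for e in entries])
        se = np.array([e[1] for e in entries])
        ns = np.array([e[2] for e in entries])
        w = 1.0 / se**2
        beta_meta = float(np.sum(w * b) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        z = beta_meta / se_meta
        p = float(np.clip(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
        q = float(np.sum(w * (b - beta_meta) ** 2))
        k = len(entries)
        i2 = float(max(0.0, (q - (k - 1)) / q)) if q > 0 and k > 1 else 0.0
        ea, oa = ref[vid]
        rows.append((vid, ea, oa, beta_meta, se_meta, p, int(ns.sum()), z, q, i2, k))
    out = pd.DataFrame(rows, columns=["variant_id", "effect_allele", "other_allele",
                                      "beta", "se", "p", "n", "z", "q", "i2",
                                      "n_cohorts"])
    return out


def top_hits(meta: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Rows with p strictly below the threshold, ascending by p."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    hits = meta[meta["p"] < threshold]
    return hits.sort_values("p").reset_index(drop=True)
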