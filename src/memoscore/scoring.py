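"""Apply weight tables to cohorts: polygenic and metabolic risk scores.

A risk score is a weighted sum of features — allele dosages for the
polygenic scores, metabolite levels for the metabolic score.  Genetic
scoring expects weights already aligned to the panel by
:func:`memoscore.dataio.harmonize_alleles` (rows flagged ``flipped`` read
dosage as ``2 - g``); missing dosages at matched variants contribute the
variant mean.  Scores are standardized within the evaluation sample, so
regression effect sizes read as "per 1 SD of the score in this sample".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataio import GenotypePanel, mean_impute, validate_weights


def score_genetic(weights: pd.DataFrame, panel: GenotypePanel):
    """Weighted dosage sum per sample, plus a coverage report.

    Returns ``(scores, report)`` where report holds ``n_weights``,
    ``n_matched`` and ``coverage`` (fraction of weight variants found in the
    panel).  An empty weight table yields zero scores with a warning.
    """
    validate_weights(weights)
    if len(weights) == 0:
        warnings.warn("empty weight table: all scores are zero", stacklevel=2)
        return np.zeros(panel.n_samples), {"n_weights": 0, "n_matched": 0,
                                           "coverage": 0.0}
    pos = {v: i for i, v in enumerate(panel.variant_ids)}
    matched = weights[weights["feature_id"].isin(pos)]
    idx = np.array([pos[v] for v in matched["feature_id"]], dtype=int)
    w = matched["weight"].to_numpy(float)
    flipped = (matched["flipped"].to_numpy(bool)
               if "flipped" in matched.columns
               else np.zeros(len(matched), dtype=bool))
    G = mean_impute(panel.dosages[:, idx]) if len(idx) else np.zeros((panel.n_samples, 0))
    G = np.where(flipped[None, :], 2.0 - G, G)
    scores = G @ w
    report = {"n_weights": int(len(weights)), "n_matched": int(len(matched)),
              "coverage": float(len(matched) / len(weights))}
    return scores, report


def score_metabolic(weights: pd.DataFrame, metabolites: pd.DataFrame) -> np.ndarray:
    """Weighted metabolite sum per sample.

    Unlike variants, every weighted metabolite must be present — a missing
    column raises with its name rather than silently dropping signal.
    """
    validate_weights(weights)
    missing = [m for m in weights["feature_id"] if m not in metabolites.columns]
    if missing:
        raise KeyError(f"weighted metabolite column(s) missing: {missing[:5]}")
    if len(weights) == 0:
        return np.zeros(len(metabolites))
    M = metabolites[list(weights["feature_id"])].to_numpy(float)
    return M @ weights["weight"].to_numpy(float)


def standardize_scores(scores: np.ndarray) -> np.ndarray:
    """Mean 0, SD 1 (ddof=1) within the given sample; zero variance raises."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance score")
    return (scores - scores.mean()) / sd
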