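"""Nested linear-model grid, incremental R^2, layered FDR, sensitivity runs.

The evaluation mirrors an incremental-prediction design: every model
regresses the episodic-memory score on a fixed background covariate set
(age at test always; blood-draw interval and ancestry PCs when metabolomic /
genomic layers are in play) plus a subset of risk scores — CAIDE, MRS, and
one of the two PRSs.  Model improvement is read from incremental R^2
(extended minus baseline, in percentage points), adjusted R^2,
predictor-specific p-values and AIC/BIC changes; no likelihood-ratio test is
used, because incremental R^2 of a nested pair is nonnegative by
construction.

AIC/BIC use the full Gaussian log-likelihood convention (additive constants
included, the error variance counted as a parameter), so values match
mainstream statistical software and only deltas are interpreted.

Multiple testing is handled by Benjamini-Hochberg step-up within declared
families: the ``within_layer`` scheme pools each data layer (CAIDE | MRS |
both PRSs together) across all models and test datasets; the ``per_prs``
scheme additionally corrects each PRS separately, guarding against the PRS
family borrowing significance from the pooled genomics layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: risk-term name -> cohort column
RISK_COLUMNS = {"caide": "caide", "mrs": "score_mrs",
                "lasso_prs": "score_lasso_prs", "gwama_prs": "score_gwama_prs"}
PRS_TERMS = ("lasso_prs", "gwama_prs")


@dataclass(frozen=True)
class ModelSpec:
    label: str
    background: tuple
    risk_terms: tuple
    outcome: str = "em_score"

    def __post_init__(self):
        if set(PRS_TERMS) <= set(self.risk_terms):
            raise ValueError("a model never combines both PRSs")

    @property
    def terms(self) -> tuple:
        return tuple(self.background) + tuple(
            RISK_COLUMNS[t] for t in self.risk_terms)


@dataclass
class ModelFit:
    spec: ModelSpec
    n: int
    r2: float
    adj_r2: float
    aic: float
    bic: float
    coef: pd.DataFrame  # term, estimate, se, t, p
    rss: float

    def term_p(self, risk_term: str) -> float:
        col = RISK_COLUMNS[risk_term]
        return float(self.coef.set_index("term").loc[col, "p"])


def fit_model(spec: ModelSpec, cohort: pd.DataFrame) -> ModelFit:
    """Least-squares fit of one model spec on complete cases.

    ``r2 = 1 - RSS/TSS``; ``adj_r2 = 1 - (1-r2)(n-1)/(n-k-1)`` with k the
    number of non-intercept terms; AIC/BIC from the full Gaussian
    log-likelihood with q = k + 2 parameters (intercept + error variance).
    Rank-deficient designs raise, naming the collinear terms.
    """
    cols = [spec.outcome, *spec.terms]
    data = cohort[cols]
    n_all = len(data)
    data = data.dropna()
    if len(data) < n_all:
        logger.info("fit_model[%s]: dropped %d incomplete cases",
                    spec.label, n_all - len(data))
    y = data[spec.outcome].to_numpy(float)
    X = np.column_stack([np.ones(len(data))]
                        + [data[t].to_numpy(float) for t in spec.terms])
    names = ["intercept", *spec.terms]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_terms(X, names)
        raise ValueError(f"rank-deficient design in model {spec.label!r}; "
                         f"collinear terms: {collinear}")
    n, ncol = X.shape
    k = ncol - 1
    if n <= ncol:
        raise ValueError(f"model {spec.label!r}: n={n} too small for {ncol} parameters")

    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    q = k + 2
    base = n * np.log(2 * np.pi * rss / n) + n
    aic = base + 2 * q
    bic = base + q * np.log(n)
    coef = pd.DataFrame(
        {"term": names, "estimate": res.params, "se": res.bse,
         "t": res.tvalues, "p": res.pvalues}
    )
    return ModelFit(spec, n, r2, adj_r2, float(aic), float(bic), coef, rss)


def _collinear_terms(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
            bad.append(names[j])
    return bad


def build_model_grid(background: list[str]) -> list[ModelSpec]:
    """The 12-model grid: background only; each single risk score; CAIDE plus
    each omics score or score pair; MRS plus each PRS.  Never both PRSs."""
    combos = [
        (),
        ("caide",), ("mrs",), ("lasso_prs",), ("gwama_prs",),
        ("caide", "mrs"), ("caide", "lasso_prs"), ("caide", "gwama_prs"),
        ("caide", "lasso_prs", "mrs"), ("caide", "gwama_prs", "mrs"),
        ("mrs", "lasso_prs"), ("mrs", "gwama_prs"),
    ]
    specs = []
    for combo in combos:
        label = "bg" if not combo else "bg+" + "+".join(combo)
        specs.append(ModelSpec(label=label, background=tuple(background),
                               risk_terms=tuple(combo)))
    return sorted(specs, key=lambda s: s.label)


@dataclass
class ComparisonRow:
    baseline_label: str
    extended_label: str
    delta_r2_pp: float
    delta_adj_r2: float
    delta_aic: float
    delta_bic: float
    added_terms: dict  # risk term -> p-value


def compare_nested(baseline: ModelFit, extended: ModelFit) -> ComparisonRow:
    """Incremental R^2 (percentage points) and AIC/BIC deltas of a nested pair."""
    if not set(baseline.spec.terms) <= set(extended.spec.terms):
        raise ValueError(
            f"{baseline.spec.label!r} is not nested in {extended.spec.label!r}")
    if baseline.n != extended.n:
        raise ValueError("nested comparison requires identical samples")
    added = [t for t in extended.spec.risk_terms
             if t not in baseline.spec.risk_terms]
    return ComparisonRow(
        baseline_label=baseline.spec.label,
        extended_label=extended.spec.label,
        delta_r2_pp=100.0 * (extended.r2 - baseline.r2),
        delta_adj_r2=extended.adj_r2 - baseline.adj_r2,
        delta_aic=extended.aic - baseline.aic,
        delta_bic=extended.bic - baseline.bic,
        added_terms={t: extended.term_p(t) for t in added},
    )


# ---------------------------------------------------------------------------
# layered FDR


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values:
    adj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def fdr_layers(records: pd.DataFrame, scheme: str = "within_layer") -> pd.DataFrame:
    """BH adjustment within declared families of risk-term p-values.

    ``records`` needs columns ``term`` (risk-term name), ``model``,
    ``dataset``, ``p``.  ``within_layer`` pools three families — CAIDE, MRS,
    and both PRSs together — across all models and datasets; ``per_prs``
    keeps one family per term (so each PRS is corrected separately).  Returns
    the records with ``family`` and ``p_adj`` columns added.
    """
    req = {"term", "model", "dataset", "p"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    out = records.copy().reset_index(drop=True)
    if scheme == "within_layer":
        fam = out["term"].map(lambda t: "prs" if t in PRS_TERMS else t)
    elif scheme == "per_prs":
        fam = out["term"]
    else:
        raise ValueError(f"unknown FDR scheme {scheme!r}")
    out["family"] = fam
    out["p_adj"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def sensitivity_exclude(cohort: pd.DataFrame, flag: str = "stroke_before_test"
                        ) -> pd.DataFrame:
    """Drop flagged rows (e.g. stroke before testing); error if nothing remains."""
    mask = cohort[flag].astype(bool)
    out = cohort[~mask].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(f"excluding on {flag!r} empties the cohort")
    return out


# ---------------------------------------------------------------------------
# grid driver


def run_grid(cohort: pd.DataFrame, background: list[str], dataset: str,
             baseline_label: str = "bg"):
    """Fit the full grid on one dataset.

    Returns ``(fits, comparisons, records)``: all ModelFits, ComparisonRows
    of every nested pair sharing the baseline's terms, and the tidy p-value
    records consumed by :func:`fdr_layers`.
    """
    specs = build_model_grid(background)
    fits = {s.label: fit_model(s, cohort) for s in specs}
    comparisons = []
    for label, f in fits.items():
        for label2, f2 in fits.items():
            if label == label2:
                continue
            if (set(f.spec.risk_terms) < set(f2.spec.risk_terms)
                    and not set(PRS_TERMS) <= set(f.spec.risk_terms)
                        | set(f2.spec.risk_terms)):
                comparisons.append(compare_nested(f, f2))
    rows = []
    for f in fits.values():
        for t in f.spec.risk_terms:
            rows.append((t, f.spec.label, dataset, f.term_p(t)))
    records = pd.DataFrame(rows, columns=["term", "model", "dataset", "p"])
    return fits, comparisons, records
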