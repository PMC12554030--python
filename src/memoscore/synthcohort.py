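"""Synthetic cohort generator with the statistical structure the study assumes.

The generator produces everything the downstream pipeline consumes, at a
desk scale standing in for the real cohorts: a genotype dosage panel with
block linkage disequilibrium, a 137-measure correlated metabolite panel with
a small truly associated subset, late-adulthood epidemiological covariates
feeding the CAIDE score, a continuous episodic-memory outcome built from an
additive genetic value, a metabolic component, the integer CAIDE score and
Gaussian noise, and an emulated external multi-cohort meta-analysis input.

Linkage disequilibrium is modeled per haplotype: within each contiguous
block, latent Gaussian liabilities follow a first-order autoregression with
coefficient ``ld_rho`` and are thresholded at the allele frequency, so
genotypes (the sum of two independent haplotypes) satisfy Hardy-Weinberg
marginals exactly while adjacent variants carry tunable (threshold-
attenuated) dosage correlation.  Metabolites are block-equicorrelated
Gaussians via a shared block factor.

Variance budgeting is by construction: the genetic, metabolic and CAIDE
components are each rescaled to their target share of unit outcome variance
in the realized sample, and the noise standard deviation makes up the
remainder, so realized variance fractions match the configuration up to the
Monte-Carlo error of the noise draw alone.

Everything is deterministic given ``SimConfig.seed``; independent substreams
are derived per stage so, e.g., regenerating genotypes alone reproduces the
same panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from . import caide as caide_mod
from .dataio import GenotypePanel
from .sumstats import run_gwas

#: unambiguous allele pairs assigned to synthetic variants
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]


@dataclass
class SimConfig:
    n_samples: int = 1001
    n_variants: int = 5000
    n_blocks: int = 50
    ld_rho: float = 0.5
    maf_range: tuple = (0.05, 0.5)
    n_causal_variants: int = 10
    h2_genetic: float = 0.3
    n_metabolites: int = 137
    n_causal_metabolites: int = 15
    metab_cor: float = 0.4
    metab_block_size: int = 10
    var_metabolic: float = 0.1
    var_caide: float = 0.02
    stroke_frac: float = 0.03
    n_external_cohorts: int = 20
    external_n_per_cohort: int = 1278
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {"n_samples": self.n_samples, "n_variants": self.n_variants,
                  "n_blocks": self.n_blocks, "n_metabolites": self.n_metabolites,
                  "n_external_cohorts": self.n_external_cohorts,
                  "external_n_per_cohort": self.external_n_per_cohort}
        for name, c in counts.items():
            if c <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.n_causal_variants > self.n_variants:
            raise ValueError("n_causal_variants exceeds n_variants")
        if self.n_causal_metabolites > self.n_metabolites:
            raise ValueError("n_causal_metabolites exceeds n_metabolites")
        if self.n_blocks > self.n_variants:
            raise ValueError("need at least one variant per LD block")
        budget = self.h2_genetic + self.var_metabolic + self.var_caide
        if budget >= 1:
            raise ValueError(f"variance budget {budget} must be < 1")
        for name, v in (("h2_genetic", self.h2_genetic),
                        ("var_metabolic", self.var_metabolic),
                        ("var_caide", self.var_caide)):
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class TrueModel:
    causal_variant_ids: list
    variant_effects: np.ndarray        # per variant, nonzero only at causals
    causal_metabolite_ids: list
    metabolite_effects: np.ndarray
    caide_effect: float                # per integer CAIDE point
    noise_sd: float
    variants: pd.DataFrame | None = None  # id, chrom, pos, alleles, maf, block

    def to_json(self, path) -> None:
        d = {
            "causal_variant_ids": list(self.causal_variant_ids),
            "variant_effects": [float(x) for x in self.variant_effects],
            "causal_metabolite_ids": list(self.causal_metabolite_ids),
            "metabolite_effects": [float(x) for x in self.metabolite_effects],
            "caide_effect": self.caide_effect,
            "noise_sd": self.noise_sd,
            "variants": (self.variants.to_dict(orient="list")
                         if self.variants is not None else None),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path) -> "TrueModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["causal_variant_ids"], np.asarray(d["variant_effects"]),
            d["causal_metabolite_ids"], np.asarray(d["metabolite_effects"]),
            d["caide_effect"], d["noise_sd"],
            pd.DataFrame(d["variants"]) if d["variants"] else None,
        )


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg_seed])


def _variant_frame(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant metadata: ids, positions, alleles, per-variant MAF, block."""
    sizes = [len(a) for a in np.array_split(np.arange(cfg.n_variants), cfg.n_blocks)]
    block = np.repeat(np.arange(cfg.n_blocks), sizes)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_variants)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS),
                                                    size=cfg.n_variants)]
    return pd.DataFrame(
        {"variant_id": [f"v{j + 1}" for j in range(cfg.n_variants)],
         "chrom": (block + 1).astype(str),
         "pos": np.arange(1, cfg.n_variants + 1) * 1000,
         "effect_allele": [p[0] for p in pairs],
         "other_allele": [p[1] for p in pairs],
         "maf": maf, "block": block}
    )


@njit(cache=True)
def _ar_threshold_sum(e, rho, thresh, n_samples):  # pragma: no cover - compiled
    """AR(1) recursion over variants, threshold to alleles, sum haplotype pairs."""
    n_hap, m = e.shape
    c = np.sqrt(1.0 - rho * rho)
    dos = np.zeros((n_samples, m))
    for i in range(n_hap):
        z = e[i, 0]
        s = i % n_samples  # haplotypes i and i+n_samples pair up
        if z < thresh[0]:
            dos[s, 0] += 1.0
        for t in range(1, m):
            z = rho * z + c * e[i, t]
            if z < thresh[t]:
                dos[s, t] += 1.0
    return dos


def _draw_dosages(variants: pd.DataFrame, n_samples: int, ld_rho: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Two AR(1)-liability haplotypes per sample, thresholded at the MAF."""
    n_hap = 2 * n_samples
    maf = variants["maf"].to_numpy()
    thresh = stats.norm.ppf(maf)
    dos = np.empty((n_samples, len(variants)))
    block = variants["block"].to_numpy()
    for blk in variants["block"].unique():
        idx = np.flatnonzero(block == blk)
        e = rng.standard_normal((n_hap, len(idx)))
        dos[:, idx] = _ar_threshold_sum(e, ld_rho, thresh[idx], n_samples)
    return dos


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Dosage panel with block-AR(1) LD and Hardy-Weinberg marginals."""
    rng = _rng(cfg.seed, 1)
    variants = _variant_frame(cfg, rng)
    dosages = _draw_dosages(variants, cfg.n_samples, cfg.ld_rho, rng)
    sample_ids = np.array([f"s{i + 1}" for i in range(cfg.n_samples)], dtype=object)
    return GenotypePanel(sample_ids, variants, dosages)


def block_partition(panel: GenotypePanel) -> list[list[str]]:
    """Variant-id lists per LD block, from the generator's block column."""
    v = panel.variants
    return [v.loc[v["block"] == blk, "variant_id"].tolist()
            for blk in v["block"].unique()]


def _scaled_component(raw: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Rescale a raw component to the target realized variance; returns the
    scaled component and the multiplier applied."""
    sd = raw.std()
    if target_var == 0 or sd == 0:
        return np.zeros_like(raw), 0.0
    mult = np.sqrt(target_var) / sd
    return (raw - raw.mean()) * mult, mult


def metabolite_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c.startswith("met")]


def simulate_cohort(cfg: SimConfig):
    """Full synthetic cohort: ``(panel, cohort_table, truth)``.

    The cohort table carries the episodic-memory outcome (continuous
    ``em_score`` plus a discretized 0-30 ``em_score_30``), CAIDE components
    and score, blood-draw interval, stroke flag, and the metabolite columns
    (``met001``..) used by the metabolome-wide analysis.
    """
    panel = simulate_genotypes(cfg)
    n = cfg.n_samples
    rng = _rng(cfg.seed, 2)

    # --- genetic component
    effects = np.zeros(cfg.n_variants)
    causal_idx = np.sort(rng.choice(cfg.n_variants, cfg.n_causal_variants,
                                    replace=False))
    if cfg.h2_genetic > 0:
        effects[causal_idx] = rng.standard_normal(cfg.n_causal_variants)
    g_raw = panel.dosages @ effects
    g, g_mult = _scaled_component(g_raw, cfg.h2_genetic)
    effects *= g_mult
    causal_variant_ids = [panel.variant_ids[j] for j in causal_idx
                          if effects[j] != 0]

    # --- metabolites: block-equicorrelated via a shared block factor
    n_met = cfg.n_metabolites
    met_names = [f"met{j + 1:03d}" for j in range(n_met)]
    met_sizes = [len(a) for a in np.array_split(
        np.arange(n_met), max(1, n_met // cfg.metab_block_size))]
    met_block = np.repeat(np.arange(len(met_sizes)), met_sizes)
    factors = rng.standard_normal((n, len(met_sizes)))
    eps = rng.standard_normal((n, n_met))
    rho = cfg.metab_cor
    M = np.sqrt(rho) * factors[:, met_block] + np.sqrt(1 - rho) * eps
    met_effects = np.zeros(n_met)
    causal_met_idx = np.sort(rng.choice(n_met, cfg.n_causal_metabolites,
                                        replace=False))
    if cfg.var_metabolic > 0:
        met_effects[causal_met_idx] = rng.standard_normal(cfg.n_causal_metabolites)
    m_raw = M @ met_effects
    m, m_mult = _scaled_component(m_raw, cfg.var_metabolic)
    met_effects *= m_mult
    causal_metabolite_ids = [met_names[j] for j in causal_met_idx
                             if met_effects[j] != 0]

    # --- CAIDE components: plausible late-adulthood marginals
    age = rng.uniform(57, 70, n)
    education = np.maximum(rng.normal(10, 3, n), 4.0)
    sbp = rng.normal(140, 18, n)
    bmi = rng.normal(27, 4, n)
    chol = rng.normal(5.8, 1.0, n)
    inactive = rng.random(n) < 0.3
    sex = np.where(rng.random(n) < 0.45, "male", "female")
    comp = pd.DataFrame(
        {"age_at_test": age, "sex": sex, "education": education, "sbp": sbp,
         "bmi": bmi, "total_chol": chol, "inactive": inactive}
    )
    caide = caide_mod.caide_score(comp)
    c, c_mult = _scaled_component(caide.astype(float), cfg.var_caide)

    # --- outcome
    noise_var = 1.0 - cfg.h2_genetic - cfg.var_metabolic - cfg.var_caide
    noise_sd = float(np.sqrt(noise_var))
    em = g + m + c + rng.normal(0, noise_sd, n)
    em_30 = np.clip(np.round(18 + 4 * em), 0, 30).astype(int)

    cohort = comp.copy()
    cohort.insert(0, "sample_id", panel.sample_ids)
    cohort["em_score"] = em
    cohort["em_score_30"] = em_30
    cohort["caide"] = caide
    cohort["draw_interval"] = np.maximum(rng.normal(2.2, 0.6, n), 0.1)
    cohort["stroke_before_test"] = rng.random(n) < cfg.stroke_frac
    cohort = pd.concat([cohort, pd.DataFrame(M, columns=met_names,
                                             index=cohort.index)], axis=1)

    truth = TrueModel(
        causal_variant_ids=causal_variant_ids,
        variant_effects=effects,
        causal_metabolite_ids=causal_metabolite_ids,
        metabolite_effects=met_effects,
        caide_effect=float(c_mult),
        noise_sd=noise_sd,
        variants=panel.variants.copy(),
    )
    return panel, cohort, truth


def simulate_external_sumstats(cfg: SimConfig, truth: TrueModel) -> list[pd.DataFrame]:
    """Per-cohort univariate summary statistics from an emulated external
    meta-analysis: each cohort is an independent draw from the same variant
    universe and genetic architecture, analysed variant-by-variant.

    Cohort sizes vary uniformly within +/-20% of ``external_n_per_cohort``.
    """
    if truth.variants is None:
        raise ValueError("truth must carry the variant frame "
                         "(run simulate_cohort first)")
    rng = _rng(cfg.seed, 3)
    tables = []
    effects = np.asarray(truth.variant_effects, dtype=float)
    for c in range(cfg.n_external_cohorts):
        n_c = int(rng.integers(int(0.8 * cfg.external_n_per_cohort),
                               int(1.2 * cfg.external_n_per_cohort) + 1))
        dos = _draw_dosages(truth.variants, n_c, cfg.ld_rho, rng)
        g_raw = dos @ effects
        g, _ = _scaled_component(g_raw, cfg.h2_genetic)
        noise_sd = np.sqrt(1.0 - cfg.h2_genetic)
        y = g + rng.normal(0, noise_sd, n_c)
        sample_ids = np.array([f"ext{c}_{i}" for i in range(n_c)], dtype=object)
        panel = GenotypePanel(sample_ids, truth.variants.copy(), dos)
        cohort = pd.DataFrame({"sample_id": sample_ids, "em_score": y})
        tables.append(run_gwas(panel, cohort, covariates=[]))
    return tables
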