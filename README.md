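# memoscore

Multiomics risk scores and incremental prediction of episodic memory.

Episodic memory (EM) — the ability to encode and recall events — declines
years before clinical dementia, which makes it a useful target for early
risk stratification. `memoscore` implements a complete, tested pipeline
that asks a concrete question: *do genomic or metabolomic risk scores
predict EM over and above classical epidemiological dementia risk factors?*
It builds four scores and compares them head-to-head in held-out samples:

- **CAIDE** — the integer cardiovascular dementia risk score (points for
  age, sex, education, systolic blood pressure, BMI, total cholesterol,
  physical inactivity; 0–15 with the default table);
- **LASSO-PRS** — a polygenic score whose weights come from a genome-wide
  L1-penalized regression of EM on allele dosages, with unpenalized
  covariates (CAIDE, age, ancestry PCs), tuned on a training/validation
  split;
- **MRS** — a metabolic risk score from the analogous metabolome-wide
  LASSO over a 137-measure NMR-style panel, tuned by 10-fold CV;
- **GWAMA-PRS** — a polygenic score whose weights are Bayesian posterior
  means of standardized effects under a continuous-shrinkage
  (gamma–gamma global–local) prior, Gibbs-sampled from inverse-variance
  fixed-effect meta-analyzed summary statistics with a block LD reference.

Predictive value is quantified with a grid of nested linear models:
for baseline terms *B* and added score *S*, the increment is
ΔR² = R²(B+S) − R²(B) in percentage points, read together with adjusted R²,
per-predictor *p*-values and ΔAIC/ΔBIC. Score *p*-values are
Benjamini–Hochberg adjusted within declared data layers (CAIDE | MRS | both
PRSs pooled) across all models and test datasets, plus a second scheme
correcting each PRS separately.

Because the motivating individual-level data are not public, the package
ships a first-class synthetic-cohort generator (`memoscore.synthcohort`)
with block-AR(1) linkage disequilibrium, Hardy–Weinberg dosages,
correlated metabolites, realistic late-adulthood covariates, an exact
variance budget (h², metabolic, CAIDE shares of the outcome), and an
emulated external multi-cohort meta-analysis — so every stage is testable
end to end against planted ground truth.

## Worked example

```bash
python examples/05_full_study.py
```

runs the whole study on a 600-sample synthetic cohort and prints:

```
train n=496, test n=104 (103 after stroke exclusion)
LASSO-PRS: 19 variants | MRS: 8 metabolites | GWAMA-PRS: 600 variants (4 genome-wide-significant hits)

incremental R^2 over the CAIDE + background model (test set):
  +gwama_prs            8.3 pp  (delta AIC   -8.1)
  +gwama_prs+mrs       19.4 pp  (delta AIC  -21.4)
  +lasso_prs            8.7 pp  (delta AIC   -8.6)
  +lasso_prs+mrs       19.5 pp  (delta AIC  -21.6)
  +mrs                 10.8 pp  (delta AIC  -11.4)

within-layer FDR-adjusted p (max across models/datasets):
term
caide        0.042
gwama_prs    0.010
...
```

Each line says how many percentage points of EM variance a score adds over
the CAIDE + background covariate model in the 104 held-out samples, and
whether the addition also improves AIC; the FDR table says which data
layers survive multiplicity control. (This demo cohort plants genetic,
metabolic *and* CAIDE signal, so all layers show up; `examples/01`–`04`
demonstrate the individual stages.)

There is also a thin CLI over the same library:

```bash
memoscore run-all --seed 1 --out study_out        # full synthetic study
memoscore simulate / caide / lasso / gwas / meta / csprs / score / evaluate
memoscore make-fixtures --out fixtures
```

## Layout

| module | role |
|---|---|
| `synthcohort` | synthetic genotypes, metabolome, covariates, outcome, external cohorts |
| `dataio` | TSV/PLINK/VCF genotype IO, tables, allele harmonization, ancestry PCs |
| `caide` | CAIDE point table (YAML-configurable) and scoring |
| `penalized` | coordinate-descent LASSO with unpenalized covariates; split/CV tuning |
| `sumstats` | vectorized per-variant OLS scan; fixed-effect meta-analysis; top hits |
| `csprs` | continuous-shrinkage Gibbs sampler over block LD; posterior-mean weights |
| `scoring` | weighted-sum scores, coverage reports, within-sample standardization |
| `evaluate` | nested-model grid, ΔR²/AIC/BIC, layered BH-FDR, sensitivity reruns |
| `pipeline` | end-to-end orchestration, config, manifest, deterministic seeding |
| `experiments` | replicated recovery and conclusion-pattern studies |

See `docs/methods.md` for the statistical details and design choices.
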