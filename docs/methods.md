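# Methods

This note documents the models, algorithms, numerical choices and
limitations of `memoscore`. Everything stated here is computed by the code;
nothing is an empirical claim beyond what the test suite and
`scripts/acceptance.py` verify at run time.

## Synthetic cohort generator

The generator stands in for non-public individual-level cohort data. It is
first-class, tested code, and its defaults define the study conditions used
throughout the tests.

**Genotypes.** Variants are partitioned into contiguous blocks (default
5000 variants in 50 blocks). Within a block, each *haplotype* carries a
latent Gaussian liability following a first-order autoregression with
coefficient `ld_rho` (default 0.5); the allele indicator is the liability
falling below the Φ⁻¹(MAF) threshold, and the dosage is the sum of two
independent haplotypes. This yields exact Hardy–Weinberg marginals at the
drawn MAF (uniform on `maf_range`, default 0.05–0.5) and a tunable,
threshold-attenuated adjacent-variant correlation; the attenuation is
checked in the tests against a 10⁶-draw Monte-Carlo oracle of the same
thresholding. The model is deliberately simpler than human LD maps — blocks
are disjoint and within-block decay is geometric — which is sufficient for
exercising LD-aware methods but does not reproduce long-range or
admixture-driven structure.

**Metabolites.** 137 measures (the size of a standard NMR metabolomics
panel), block-equicorrelated via a shared Gaussian factor per block of 10
(default within-block correlation 0.4); 15 are truly associated with the
outcome by default.

**Covariates and outcome.** CAIDE components use plausible late-adulthood
marginals: age ~ U(57, 70), education ~ N(10, 3) truncated ≥ 4 years,
SBP ~ N(140, 18) mmHg, BMI ~ N(27, 4) kg/m², cholesterol ~ N(5.8, 1.0)
mmol/L, inactivity ~ Bernoulli(0.3), male sex ~ Bernoulli(0.45). The
blood-draw-to-test interval is N(2.2, 0.6) years and a stroke flag is set
for a 3% fraction. The continuous EM outcome is

y = g + m + γ·CAIDE + ε,

where g = Xβ_g (10 causal variants by default), m = Mβ_m, and each
component is *rescaled in the realized sample* to hit its configured
variance share (defaults h² = 0.30, metabolic 0.10, CAIDE 0.02 of unit
total variance); ε makes up the remainder. Realized fractions therefore
match the configuration up to the Monte-Carlo error of the noise draw
alone. CAIDE enters through the integer score, not its raw components. A
discretized 0–30 word-list-style version of the outcome (`em_score_30`) is
emitted alongside the continuous one; the analyses use the continuous
score.

**External meta-analysis.** Each of `n_external_cohorts` (default 20)
cohorts is an independent draw from the same variant universe and genetic
architecture, sized uniformly within ±20% of `external_n_per_cohort`
(default 1278, i.e. ~25k total), analyzed variant-by-variant and pooled by
fixed-effect inverse-variance weighting. All cohorts share a common trait
scale — real meta-analyses harmonize heterogeneous tests upstream, which is
out of scope here.

**Determinism.** Every stage derives an independent substream from the
configured seed; identical configurations reproduce outputs byte for byte,
and different seeds give different data.

## CAIDE score

The default point table is the original midlife, non-APOE model: age > 53 →
4 points, 47–53 → 3; education < 7 years → 3, 7–9 → 2; male → 1;
SBP > 140 mmHg → 2; BMI > 30 kg/m² → 2; cholesterol > 6.5 mmol/L → 2;
inactive → 1 (maximum 15). Thresholds for the continuous components are
strict (">"), applied as printed in the source model. The table is
configuration (YAML), not a constant, since cohort-specific variants exist.
Missing components raise — the score is never silently imputed.

## Penalized regression (LASSO-PRS, MRS)

The estimator minimizes

(1/2n)‖y − X_u a − X_p b‖² + λ‖b‖₁,

with covariates X_u (intercept; CAIDE and age; ancestry PCs for the
genome-wide fit; blood-draw interval for the metabolome-wide fit) never
shrunk. Because the penalty touches only `b`, the problem is solved by
residualizing y and the penalized block against X_u once (Frisch–Waugh) and
running cyclic coordinate descent with soft-thresholding, warm starts down
a decreasing λ grid, and glmnet-style full-sweep/active-set iteration; `a`
is recovered by an exact least-squares solve afterwards. The hot loop is
numba-compiled. Convergence is declared when the largest scaled coefficient
update falls below `tol` (default 1e-7); the tests certify KKT conditions
and agreement of the objective with a generic convex-solver oracle to 1e-6
on small instances.

Numerical conventions: features are mean-imputed, zero-variance columns
dropped with a log entry, standardization uses the 1/n variance convention,
and the default grid is 100 log-spaced values from λ_max down to
0.001·λ_max. Exported weights are back-transformed to the raw per-allele /
per-metabolite-unit scale.

Tuning follows two protocols: a single 80/20 training/validation split for
the genome-wide fit and 10-fold CV for the metabolome-wide fit, both
choosing the λ with minimum validation MSE and refitting on the full
sample at that λ. The min rule (not 1-SE) is used because the analysis
expects a relatively liberal selected set; both the fraction/fold count and
the rule are configurable. One consequence, verified by direct simulation:
under a pure-noise response the chosen model is very sparse but not
reliably empty — validation noise lets a handful of features in. The
pipeline therefore falls back to the best-loss λ selecting ≥ 1 feature when
the minimum is empty, so downstream evaluation always has a non-degenerate
score column; an empty selection would otherwise leave the layer's
p-values undefined.

## Per-variant scan and meta-analysis

`run_gwas` fits, for every variant, OLS of the outcome on dosage +
covariates + intercept. With a shared covariate block this reduces exactly
(Frisch–Waugh–Lovell) to simple regression on residualized quantities and
vectorizes across the panel; betas, SEs and t-based p-values match a
reference per-variant OLS to 1e-8. Monomorphic variants are flagged with
missing effects. `meta_fixed` pools cohorts with weights 1/se²
(fixed-effect only, no genomic control), reports Cochran's Q and I² without
acting on them, harmonizes alleles across cohorts by sign-flipping, and
meta-analyzes partially observed variants over the cohorts that have them.
Genome-wide significance uses strict p < 5×10⁻⁸.

## Continuous-shrinkage posterior weights (GWAMA-PRS)

Standardized marginal effects (z/√n) and a block LD reference feed a Gibbs
sampler over the global–local gamma–gamma hierarchy

β_j ~ N(0, (σ²/n)ψ_j), ψ_j ~ Gamma(a, δ_j), δ_j ~ Gamma(b, φ),

with block-wise multivariate-normal β updates given LD
(β_blk ~ N(A⁻¹β̂, (σ²/n)A⁻¹), A = R + diag(1/ψ)), a conjugate
inverse-gamma σ² update, generalized-inverse-Gaussian ψ updates, conjugate
gamma δ updates, and — when φ = "auto" — a fully Bayesian φ update through
an auxiliary variable. Defaults a = 1, b = 0.5, 1000 iterations with 500
burn-in and thinning 5 follow the reference parameterization of this prior
family; replicated experiments in the tests use 300-iteration chains, which
is enough for the rank-order comparisons they make. With a = 1 the ψ
conditional has GIG order 1/2 and is drawn by fast vectorized
inverse-Gaussian sampling (ψ = 1/Y with Y inverse-Gaussian); other orders
use scipy's generalized-inverse-Gaussian sampler. σ² starts at 1, β at 0;
ψ is clipped to [1e-12, 1e12] for numerical safety only. A fixed-σ²
mode exists so the single-variant posterior can be validated against 1-D
numerical quadrature (the tests require agreement within 2%).

Block correlation matrices are estimated from standardized reference-panel
dosages and eigenvalue-floored at 1e-6, so duplicated or perfectly
collinear variants cannot break the Cholesky factorization. Posterior
means are divided by the reference panel's dosage SDs to yield per-allele
weights. The effective n is the median per-variant meta-analysis n.

## Scoring

Genetic scores are weighted dosage sums after allele harmonization:
variants are matched by id; a weight whose effect allele equals the panel's
other allele (directly or by strand complement) reads the dosage as 2−g;
strand-ambiguous (A/T, C/G) panel variants are dropped, a policy chosen
over frequency-based resolution because weight tables are not guaranteed to
carry frequencies. Coverage (fraction of weight variants found) is
reported. Missing dosages at matched variants contribute the variant mean.
Metabolite scores require every weighted measure to be present — a missing
column is an error, not a silent drop. All scores are standardized to mean
0, SD 1 (ddof = 1) *within each evaluation sample*, so regression effects
read per 1 SD in that sample; this follows the study design rather than
train-moment standardization, and changes interpretation, not fit.

## Evaluation

The model grid holds the background covariates fixed per dataset (age
always; blood-draw interval and ancestry PCs whenever the metabolomic or
genomic layer is in play anywhere in the grid) so that R² differences are
attributable to the risk scores alone. Twelve specifications are fitted:
background only; each single score; CAIDE plus each omics score or pair;
MRS plus each PRS — never both PRSs together. For nested pairs the report
carries ΔR² in percentage points (nonnegative by construction), Δadjusted
R², ΔAIC, ΔBIC and added-term p-values; no likelihood-ratio test is used.
AIC/BIC include the Gaussian constants and count the error variance as a
parameter (q = k + 2), matching mainstream statistical software, and only
deltas are interpreted. Complete-case analysis throughout.

Benjamini–Hochberg step-up adjustment (adj₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j, capped
at 1) is applied within two family schemes: *within-layer* pools
{CAIDE}, {MRS}, {LASSO-PRS ∪ GWAMA-PRS} across all models and both test
datasets (with and without stroke exclusion); *per-PRS* gives each PRS its
own family, guarding against the pooled genomics family borrowing
significance. The in-repo implementation is checked against an independent
step-up oracle on 1000 random vectors.

The stroke-exclusion sensitivity analysis drops flagged participants
(3 of 104 at the default flag rate) and reruns the identical grid; the
children-transfer stage scores the adult-derived PRS weight tables in
simulated child cohorts (defaults n = 309 and n = 443, with 93%/94.5%
variant overlap to mirror incomplete imputation), adjusting for child age,
sex and maternal education. By default the child outcome carries no genetic
signal, so the expected transfer result is null.

## Replicated experiments and problem sizes

`memoscore.experiments` packages two replicated studies used by the
acceptance layer. The *recovery* experiment runs at the generator's default
desk scale (1001 samples, 5000 variants, h² = 0.3 over 10 causals, external
meta of 20 × ~1278) and measures the held-out correlation of the LASSO-PRS
with the true genetic value and of posterior-mean vs marginal effects with
the true effects. The *conclusion-pattern* experiment runs the full
pipeline with a planted genetic signal and null metabolome/CAIDE at test
n = 104, on a 2000-variant panel and a 10 × 1000 external meta — a size
chosen so twenty replicates remain a desk-scale computation — and checks
that the within-layer FDR marks both PRSs significant and neither null
layer. Passing these says the machinery recovers planted signal under the
generator's assumptions; it does not certify performance on real cohorts,
whose LD, ascertainment and measurement properties the generator
simplifies.

## Known limitations

- No population-stratification confounding is simulated by default
  (ancestry PCs are supported downstream but PC adjustment is exercised on
  unstructured panels).
- BGEN/PGEN input, liftover and INFO-score filtering are out of scope;
  PLINK bed IO is hard-call only.
- The meta-analysis assumes a common trait scale across cohorts.
- Fixed-effect pooling only; heterogeneity statistics are reported, never
  acted on.
- LASSO produces point selections without inference; significance
  statements attach only to the score-level regression coefficients.
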