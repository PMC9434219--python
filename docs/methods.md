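# Methods

`phenogp` implements a comparative genomic-prediction (GP) versus
phenomic-prediction (PP) analysis for growth traits in three-way hybrid
(H3W) families, together with a synthetic-data generator that reproduces the
study's data structure with known ground truth. This note documents the
models, the generator, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## The synthetic study

### Cross structure

Two half-sib families are produced by crossing a clonally propagated,
highly heterozygous F1 parent to two mostly homozygous landrace lines.
Parental diploid genomes are drawn per site to hit target heterozygosity
fractions — defaults 0.84 for the shared F1 parent and 0.14 / 0.12 for the
two line parents, matching the relative heterozygosity levels reported for
such material. Each offspring receives one random gamete from each parent,
independently per site: there is **no linkage map and no LD**; marker codes
are additive alt-allele dosages in {0, 1, 2}. Default family sizes are 74
and 119 with 2,000 markers (a desk-scale stand-in for array-scale marker
counts), 20 QTL per trait with disjoint QTL sets across traits.

### Trait model

For individual *i*, trait *t*, condition *c*:

```
y_itc = mu_t + g_it + E_tc + (GxE)_itc + eps_itc
```

with `g = (X - mean(X)) B` from the sparse marker effects, condition
effects `E_tc` drawn once per condition, and i.i.d. normal G×E deviations
and residuals. **Every realized component is rescaled in-sample to its
configured variance exactly** ("variance-exact" simulation). This is a
deliberate generator choice: with only three conditions the realized
variance of three normal draws scatters as a chi-square with two degrees of
freedom, which would dominate any recovery experiment; exact scaling makes
the ground truth sharp without changing the model class. Default components
are (var_G, var_E, var_GxE, var_eps) = (1, 1, 0.6, 0.6) per trait, giving a
broad-sense heritability of 0.4167 under the partition formula below — a
mid-range value between the study traits' extremes.

In `simulate_study` (two families, shared F1 parent) the marker effects are
shared and scaled on the pooled population so that the genetic architecture
transfers across families; per-family realized components are then
approximate rather than exact.

### ChlF model

The 18 chlorophyll-fluorescence (OJIP) parameters are generated per
condition as

```
chlf_ikc = shift_kc + sqrt(h2_k) * gamma_ik + sqrt(1 - h2_k) * noise_ikc
gamma_ik = sum_t rho_tk * std(g_it) + sqrt(1 - sum_t rho_tk^2) * own_ik
```

where `rho` is the configurable trait × ChlF genetic-loading matrix,
`own_ik` is a ChlF-specific genetic component driven by its own QTL
(standardized), and `shift_kc` is a condition shift. By construction the
Pearson correlation between the ChlF *genetic component* `gamma_k` and the
trait genetic value is `rho_tk` in expectation. The per-parameter genetic
share `h2_k` defaults to 0.38 for parameters that carry a nonzero trait
loading and 0.10 for the rest: under the heritability formula below this
puts loaded parameters at a broad-sense H² of about 0.24 (the top of the
ChlF heritability range such studies report, and it is the
photosynthetic-performance parameters that correlate with growth) and
leaves the rest barely heritable. Default loadings place maxima of
0.35/0.38/0.30 on a few parameters per trait; `chlf_dominant_loading()`
provides the contrasting regime in which ChlF carries most of the
trait-genetic signal (four parameters per trait at 0.45), used for
end-to-end GP-versus-PP comparisons.

The generator emits one value per plant × condition × parameter, i.e. the
nightly replicate measurements of a fluorimeter campaign are taken as
already averaged; measurement replication structure is not modeled.

### What the generator does not emulate

No linkage/LD, no dominance or epistasis, no pedigree beyond the single
cross, no selection, no spatial field effects, Gaussian components
throughout. Passing recovery tests on this generator demonstrates that the
estimators are correct under their own assumptions — not that real
fluorescence data carry this much (or this linearly structured) signal.

## Genotype quality control

Markers are removed when the folded allele frequency (computed on
non-missing calls) is **strictly below 0.05** or the call rate is strictly
below 0.95; a marker at exactly the MAF threshold is kept. Samples are
removed when their missing fraction **strictly exceeds 0.10** or when they
lack a match in the phenomic or trait panel. Filter order: markers, then
samples, then a marker re-check (sample removal can change call rates),
then mean imputation (real-valued marker means, never rounded). The
QC report's bookkeeping (in − removed = out on both axes) is asserted.

## Prediction models

All penalized objectives are exposed on the unscaled convention
`||y − Xb||² + λ·penalty(b)`. Predictors are standardized per column
(training statistics only; a switch disables it), responses are centered;
intercepts are unpenalized.

- **RR** — closed form, primal `(X'X + λI)^{-1}X'y` or dual
  `X'(XX' + λI)^{-1}y` depending on shape; grid fits share one
  eigendecomposition.
- **mLASSO** — elementwise L1 on the (multi-response) coefficient matrix.
  The objective separates across response columns, so each column is an
  independent LASSO solved by scikit-learn coordinate descent with
  `alpha = λ/(2n)`; grids use warm-started `lasso_path`.
- **EN** — `||y − Xb||² + λ1||b||² + λ2||b||₁` (λ1 multiplies the L2 term,
  λ2 the L1 term); mapped to scikit-learn as
  `alpha = (λ2 + 2λ1)/(2n)`, `l1_ratio = λ2/(λ2 + 2λ1)`; the λ2 = 0 and
  λ1 = 0 edges are special-cased to the exact ridge/LASSO solutions.
- **GBLUP** — `y = 1μ + u + ε`, `u ~ N(0, σu²K)` with `K = ZZ'` on the
  column-centered marker matrix (optional `K = ZZ'/p`). Variance components
  by profile REML: the intercept is projected out, the eigenvalues of
  `P(K + I)P` separate the removed direction, and the REML criterion is
  maximized over `log10 δ ∈ [−8, 8]` (`δ = σε²/σu²`) by bounded scalar
  minimization. Predictions use the cross-relationship block, equivalently
  the stored ridge-equivalent marker effects; the RR-BLUP identity
  (GBLUP ≡ marker ridge at λ = σε²/σu²) is enforced by test. The diagonal
  of K is ridged by 1e-8.
- **BL** — Bayesian LASSO via the normal–exponential scale mixture;
  single-site Gibbs updates with running residuals (numba-compiled),
  conjugate draws for the intercept, coefficients, mixing variances
  (inverse-Gaussian), residual variance, and λ² with a Gamma(1, 0.1)
  hyperprior. Default chain 20,000 / 5,000 burn-in; all chains are seeded
  and bit-reproducible.
- **mBayesB** — multi-trait BayesB: per locus a t-vector of inclusion
  indicators (any of the 2^t patterns), latent effects
  `β_j ~ N(0, Σ_j)` with locus-specific `Σ_j ~ IW(t + 4, 0.1·I)`, prior
  inclusion probability π = 0.05 (all config-exposed), residual covariance
  sampled from its inverse-Wishart full conditional. Indicators and effects
  are sampled jointly per (locus, trait) with the effect integrated out of
  the inclusion odds; the locus precision update uses the Sherman–Morrison
  identity on the fixed prior scale. Posterior means of the realized
  effects and per-locus per-trait inclusion frequencies are returned.
- **L21-joint** — row-sparse multivariate regression with joint sparse
  precision estimation: alternating minimization of
  `tr[(1/s)(Y − XB)Ω(Y − XB)'] − log|Ω| + λ1||Ω||₁,off + λ2||B||₂,₁`
  with `s` the training sample count. The B-step is proximal gradient
  (ISTA with backtracking, rowwise group soft-threshold; gradients formed
  as `X'((XB − Y)Ω)` so wide designs stay O(npt) per step); the Ω-step is
  the graphical lasso on the residual scatter (off-diagonal L1 penalty,
  scikit-learn backend; λ1 = 0 inverts the scatter directly, ridged by
  1e-6 when near-singular). Ω starts at the identity and B is updated
  first — estimating Ω from the zero-coefficient residuals would absorb
  unfit signal as "correlated noise" before the regression can explain it.
  The tracked joint objective is non-increasing across alternations;
  stopping at relative change 1e-6 or 500 alternations.

Hyperparameter grids (for RR/mLASSO/EN/L21-joint): 20 logarithmic points on
`[1e-4·λmax, λmax]` with `λmax = 2·max|X's(y − ȳ)|`; the elastic net crosses
that grid with 5 mixing levels; L21-joint uses a 3×3 grid built from the
row-group threshold analogue and the response variance scale. Bayesian
models and GBLUP carry no tuning grid.

## Evaluation

Predictability is the Pearson correlation between predicted and observed
values in the validation set, **NA when either vector has zero standard
deviation** (e.g. an all-zero LASSO fit). Repeated K-fold cross-validation
(K = 3, 20 repetitions by default) with nested 3-fold hyperparameter
selection on the outer-training data; folds are deterministic given
(seed, repetition) and train/test id disjointness is asserted on every
split. Aggregation: traits within a fold, then folds, then repetitions; NA
repetitions are excluded from means and counted. Standard errors are over
repetition means.

Settings: **S1** concatenates the three post-acclimation conditions
(9 response columns; ChlF predictors 54 columns, SNP predictors the full
marker matrix). **S2** restricts responses to the shade/AFS condition;
its augmented variant widens ChlF predictors to all conditions (SNP
predictors are unchanged by augmentation, so the augmented run applies to
PP only). **S3** (condition-ahead) trains on one condition and predicts the
first 20 lines (stored input order; a seeded permutation is available) in
the next, pairs (2→3), (3→4), (2→4), with those 20 lines excluded from
training; hyperparameters are tuned on the training condition only. **S4**
trains on one family and scores the other per trait × condition over the
shared predictor columns, both directions. GBLUP, being a
genomic-relationship model, is evaluated with SNP predictors only.

Selection ability ranks all lines by observed and by out-of-fold predicted
value and reports the percentage overlap of the top (or bottom) 20 sets;
ties break by stable input order. The family-level comparison applies the
two-sample Hotelling T² (pooled covariance, exact F transform) to the
methods × 9-trait mean-predictability matrices of the two families, with
methods as observations.

## Quantitative genetics

Variance partition `y = μ + G + E + G×E + ε` with all effects random:
balanced designs use the exact ANOVA estimators (identical to REML inside
the parameter space); unbalanced designs fall back to EM-REML (500
iterations, relative tolerance 1e-8); negative estimates are truncated to
zero and flagged. With one observation per genotype × condition cell the
interaction and residual are confounded: the lumped mean square is reported
as `var_eps` with `var_GxE = 0` and `gxe_confounded=True`. Broad-sense
heritability is

```
H² = σG² / (σG² + σE² + σGxE²/e + σε²/e)
```

with `e` the number of conditions — note σE² enters **undivided** by `e`;
this unusual form is the primary definition here, with the conventional
σE²-free denominator available behind a switch. H² is insensitive to the
G×E/residual confounding because both terms are divided by `e`.

Genetic effects are genomic BLUPs from the marker-ridge (rrBLUP ≡ GBLUP)
model per trait × condition — identically for the growth traits and the 18
ChlF parameters — and the genetic correlation matrix is the Pearson
correlation of those BLUP vectors (3 traits × 3 conditions by 18 ChlF ×
3 conditions = 9 × 54), with zero-variance vectors flagged NaN. Because
each BLUP carries estimation noise, this estimator is attenuated toward
zero; recovery experiments therefore use a calibration profile (n = 200,
300 markers, 15 QTL per trait) where the BLUPs are informative. An
in-sample BLUP always correlates positively with its own training response
(it is a positive-semidefinite smoother), so the meaningful null check is
that genetic effects estimated from independent responses are mutually
uncorrelated.

## Problem sizes and profiles

Full-scale chain defaults (20,000 / 5,000) are kept on the fit functions.
End-to-end runs and the acceptance script use the package's desk-scale
profile (`evaluate.DESK_PROFILE`): 2 repetitions of 3-fold nested CV,
BL chains 400/100, mBayesB chains 200/50, 6-point λ grids with 2 mixing
levels, a 2×2 L21 grid with 40 alternations × 60 proximal steps, and
coordinate-descent tolerance 1e-3. These sizes were chosen so a full
two-family, five-setting, seven-model run completes on a single CPU in
minutes while leaving every qualitative contrast (GP vs PP, transfer decay,
selection overlap) intact; shortened chains mainly add Monte-Carlo noise to
individual predictability estimates.

## Known limitations

- No LD between markers: genomic prediction leans entirely on the causal
  markers themselves, so GP predictabilities at desk scale are lower than
  array-scale studies with LD would give; the GP-vs-PP contrast is the
  designed target, not the absolute GP level.
- The joint L21 objective is non-convex in (B, Ω) jointly; alternating
  minimization guarantees monotone descent, not a global optimum (the
  identity initialization avoids the degenerate "correlated-noise" basin).
- The EM-REML fallback is O(n³) per iteration and intended for modest
  unbalanced designs, not field-scale data.
- Hotelling's T² treats methods as independent observations of family
  performance, a pragmatic reading rather than a calibrated test.
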