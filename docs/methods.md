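# Methods

## Estimation

**TSLS.** For a single endogenous exposure *x*, excluded instruments
*Z* (n×k), included exogenous covariates *W* (n×q) and an intercept,
the estimator solves the projected normal equations
β̂ = (X'P X)⁻¹ X'P y with X = [1, W, x] and P the projection onto
[1, W, Z]. Internally, when an intercept is present all variables are
mean-centred before solving (Frisch–Waugh): slopes, their covariance
block and residuals are unchanged, and the conditioning of the normal
equations improves by orders of magnitude when variables have large
means (the simulation confounder has mean 10). This is what makes the
single-instrument TSLS ≡ Wald-ratio identity hold to 1e−10 rather than
1e−9.

**Standard errors.** Classical homoskedastic TSLS covariance
σ̂²(X̂'X̂)⁻¹ with residuals computed at the *original* exposure
(never the first-stage fit) and σ̂² = RSS/n — the convention of the
standard econometric IV commands, paired with normal (1.96) intervals.
Plain OLS uses the textbook RSS/(n−p). The statsmodels sandbox IV2SLS
implementation, which uses RSS/(n−p), serves as an independent
cross-check in the tests: point estimates agree to 1e−10 and SEs after
the √(n/(n−p)) rescaling.

**First stage.** R² and F refer to the excluded instruments; with
covariates both are partial (exposure and instruments residualised on
[1, W]). Degrees of freedom are (k, n−k−q) where q counts exogenous
regressors including the intercept, so that F = [R²/(1−R²)]·[(n−k−1)/k]
holds exactly in the covariate-free case. If the instruments span the
exposure exactly, TSLS is still defined (and equals OLS); only F
degenerates and is reported as +∞.

## Diagnostics

*Sargan*: n·R² from regressing TSLS residuals on the full instrument
set, χ² with L−1 df; verified identical (1e−10) to the quadratic-form
expression u'Z(Z'Z)⁻¹Z'u/σ̂². Returned as explicitly not-applicable
for just-identified models. The Hansen J is not provided — the package
works in the homoskedastic setting throughout.

*Durbin–Wu–Hausman*: control-function form. The first-stage residual
v̂ is added to the structural OLS regression; the Wu–Hausman F is the
squared t on v̂ (F(1, n−p)), the Durbin statistic the score form
n·(RSS_r−RSS_u)/RSS_r (χ²₁). Both are reported; the headline `p` is
the F form. The two agree closely at large n (their p-values differ by
<0.01 at n = 10⁵ in the tests).

A caution established by the test suite: the Sargan χ² null
approximation needs non-weak instruments. Under the four-SNP simulation
design below (average F ≈ 13.5, two instruments with F < 10) its type-I
error at α = 0.05 is ≈ 0.073 at n = 5,000; with the genotype effects
scaled ×10 it is nominal. The calibration test therefore runs the
strong-effect null; applied users should read Sargan p-values near the
threshold cautiously when instruments are weak.

*Balance screen*: per-allele associations of each genotype with
declared potential confounders, in the spirit of an RCT baseline table
— linear coefficient for continuous covariates, logistic odds ratio
for binary, χ² over genotype classes for categorical (statsmodels /
scipy fits). P-values are reported raw; imbalances at the chance rate
are expected and the table is meant to be read as a whole.

## Allele scores

Unweighted: score = Σ_j G_ij. Internal weights: univariable slope of
the exposure on each SNP, score = Σ w_j G_ij / Σ w_j. This is the
construction the simulations monitor; a `joint=True` option instead
uses the joint first-stage coefficients, which makes score-TSLS
coincide with multi-instrument TSLS exactly in-sample (with
independent instruments the univariable version converges to the same
thing — the tests check agreement to 0.005 at n = 10⁵). External
weights are caller-supplied (two-column CSV). Missing genotypes
propagate strictly (missing any constituent → missing score);
mean-imputed dosages sit behind an off-by-default flag. Internal-weight
scores carry a warning that their single-df F overstates instrument
strength.

## Data handling

Genotypes are additive dosages, 0/1/2 counts of an effect allele that
must be declared explicitly (per SNP) in the schema; allele-pair
strings ("TA", "T/A") and pre-coded dosages are both accepted, and
flipping the declared effect allele maps g → 2−g. Missing codes
(default "", "NA", ".", "./.") become NaN and are never silently
dropped: the `MissingnessPolicy` decides between one common
complete-case sample across all instruments and per-model maximum-n
samples, and an accounting table reports the n retained per SNP and
jointly. VCF input (biallelic, GT field) goes through cyvcf2.

The HWE test is the Pearson χ² with 1 df against expectations from the
sample allele frequency — chosen over the exact test because it
reproduces the worked genotype-count examples in the test suite at
2 dp; monomorphic variants return p = 1 with a flag. Trait
standardisation is log-transform followed by linear residual-adjustment
for age and sex and scaling to unit SD (regression rather than binning;
the choice is invisible at the precision reported downstream).

## Simulation engine

DGP: independent G_j ~ Binomial(2, p_j), U ~ N(mean, sd),
X = Σ a_j G_j + U, Y = βX + U. Presets:

* `sim2` — the fully specified weak/strong design: frequencies
  (0.4, 0.2, 0.2, 0.4), per-allele effects (0.1, 0.1, 0.05, 0.05),
  U ~ N(10, 1), β = 1, n = 5,000. Analytic Var(X) = 1.01, so OLS is
  biased by 1/1.01 ≈ 0.990 and the four instruments explain ≈1% of
  exposure variance — mirroring the tiny R² typical of adiposity SNPs.
* `sim1` — a three-SNP strong-instrument design *calibrated, not
  transcribed*: the printed cumulative first-stage R̄² profile
  (0.1163, 0.1898, 0.2212) pins down Var(X) = 1/(1−0.2212) and each
  SNP's variance share; with frequencies fixed at 0.3 the coefficients
  follow in closed form (0.596, 0.474, 0.310). This profile implies a
  large-sample OLS bias of 1/Var(X) = 0.779; a reported OLS bias of
  0.8194 for the same design is arithmetically incompatible with the
  R̄² triple under this DGP structure, so the R̄² constraints are the
  ones honoured and the design is used only for the calibration
  property and qualitative orderings.

The Monte Carlo harness fits every requested estimator (OLS, TSLS on
subsets, TSLS on unweighted/weighted scores — weights re-estimated
within each replication) on the *same* dataset per replication, and
summarises bias, MSE, average SE, 95% coverage, average first-stage R²
and F, and the mean per-replication |TSLS bias|/|OLS bias| ratio (the
ratio of averaged biases is also emitted for transparency), each with
its Monte Carlo SE. One master seed spawns an independent PCG64
substream per replication, so summaries are bit-reproducible and
extending the estimator list never perturbs the draws. Replications
where an estimator is singular (e.g. a monomorphic genotype draw) are
dropped and counted, with a 1% abort threshold. Power curves
re-simulate the DGP across a grid of true β values and apply the
normal-critical-value Wald test of β = β₀ (coverage and tests both use
1.96, i.e. normal rather than t critical values).

## Problem sizes and what passing shows

The acceptance script runs the full 10,000 × n=5,000 study (≈25 s,
single CPU); the test suite's reproduction test uses 2,000
replications with the comparison band widened by √(10000/2000), and
the calibration/coverage/size checks use 1,000 replications against
binomial bounds. The generator draws instruments that are genuinely
independent, confounding that is exactly additive and errors that are
homoskedastic Gaussian — so passing results validate the estimators
and their finite-sample behaviour under the stated model, not
robustness to LD between variants, pleiotropy, non-linearity,
heteroskedasticity or informative missingness, none of which the DGP
emulates. The synthetic cohort fixture adds realistic surface
structure (log-normal traits, age/sex effects, per-SNP missingness at
2–8% so the joint complete-case sample narrows to ≈85%) but shares the
same idealisations.

## Known limitations

Single endogenous exposure only; no LIML/Fuller or other
weak-instrument-robust estimators; no binary-outcome (non-linear) IV
models; no genotype imputation (missingness is handled by explicit
complete-case policies); robust SEs exist behind a flag but the
reported conventions are homoskedastic throughout.
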