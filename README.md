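# mriv — Mendelian randomisation with multiple genetic instruments

`mriv` estimates the causal effect of a modifiable exposure on a
continuous outcome using genetic variants as instrumental variables
(Mendelian randomisation), with an emphasis on what changes when
*several* instruments are available: precision gains, weak-instrument
bias, testability of the IV assumptions, allele-score instruments and
the missing-data cost of requiring complete genotypes.

It is written for epidemiologists and biostatisticians running
individual-level MR analyses (cohort tables or VCF genotypes) and for
methodologists running simulation studies of IV estimators.

## The model

For individual *i* with outcome *Y*, exposure *X*, genotypes
*G₁…G_L* (coded additively 0/1/2 as counts of an effect allele) and
unmeasured confounder *U*, the linear IV model is

    X_i = Σ_j a_j G_ij + U_i + ε_i,        Y_i = β X_i + U_i + η_i,

where each *G_j* must be (1) associated with *X*, (2) independent of
*U*, and (3) independent of *Y* given *X* and *U*. OLS of *Y* on *X* is
biased by Cov(X,U)/Var(X); the two-stage least squares (TSLS) estimator
projects *X* onto the instruments (plus covariates and an intercept)
and regresses *Y* on the projection, recovering β when the assumptions
hold. Standard errors are classical homoskedastic TSLS standard errors
with residuals evaluated at the original exposure and error variance
RSS/n; intervals use the normal multiplier 1.96.

Instrument strength is summarised by the first-stage R² and
F = [R²/(1−R²)]·[(n−k−1)/k] for k instruments; the relative bias of
TSLS toward OLS is approximately 1/F, which is why F < 10 flags a weak
instrument. With L ≥ 2 instruments the Sargan statistic (n·R² of the
TSLS residuals regressed on all instruments, χ² with L−1 df) tests
whether the instruments agree, and the Durbin–Wu–Hausman
control-function test compares OLS with TSLS. Allele scores — the
(optionally weighted) sum of risk-allele counts, used as a single
instrument — trade the over-identification test for a higher
single-degree-of-freedom F.

## Worked example

Generate a synthetic genotyped cohort (four adiposity-style SNPs with
per-SNP missingness, a shared confounder, log-normal traits) and fit the
full model battery:

```sh
mriv fixture --out demo/cohort.csv --n 4000 --seed 11
mriv fit --cohort demo/cohort.csv --schema demo/cohort.schema.yaml --out demo/estimates.csv
```

which prints (reformatted; `estimate` is the ratio of geometric mean
outcome per SD of log exposure, since both traits are log-transformed
and age/sex z-scored):

```
                    model    n  fs_r2   fs_F  estimate  ci_low  ci_high  hausman_p  sargan_p
                      OLS 3371    NaN    NaN     1.718   1.671    1.767        NaN       NaN
                   IV FTO 3371  0.003 10.030     1.617   0.965    2.708      0.816       NaN
                IV GNPDA2 3371  0.001  1.833     1.803   0.541    6.006      0.938       NaN
                  IV MC4R 3371  0.007 22.540     1.725   1.224    2.433      0.981       NaN
                IV TMEM18 3371  0.002  5.544     1.468   0.726    2.967      0.655       NaN
            IV FTO+GNPDA2 3371  0.004  5.959     1.644   1.025    2.638      0.855     0.871
       IV FTO+GNPDA2+MC4R 3371  0.010 11.622     1.697   1.287    2.239      0.930     0.974
IV FTO+GNPDA2+MC4R+TMEM18 3371  0.012 10.230     1.663   1.288    2.148      0.801     0.978
      IV unweighted score 3371  0.004 14.074     1.762   1.141    2.721      0.910       NaN
        IV weighted score 3371  0.012 40.917     1.663   1.287    2.148      0.800       NaN
```

Read it as: each single SNP gives a noisy IV estimate (wide CIs; two
SNPs are weak, F < 10); combining all four SNPs shrinks the CI; the
Sargan p-values give no evidence that the instruments disagree; the
internally weighted allele score reproduces the four-instrument TSLS
row with a flattered single-df F. The complete-case sample (n = 3371 of
4000) reflects the per-SNP missingness; a companion
`.missingness.csv` accounts for the n retained per SNP.

Other subcommands: `mriv screen` (HWE and genotype–confounder balance
tables), `mriv score` (allele scores with internal/external weights),
`mriv simulate` and `mriv power` (Monte Carlo summaries and power
curves for built-in or YAML-specified data-generating processes).

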