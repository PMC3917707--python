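"""Instrument-validity diagnostics.

Three screens for the IV assumptions:

* Sargan over-identification test — with L >= 2 instruments for one
  exposure, tests whether the instruments give mutually consistent
  causal estimates.  The statistic is n.R^2 from regressing the TSLS
  residuals on the full instrument set, referred to chi-square with
  L - 1 degrees of freedom.  Not defined for just-identified models.
* Durbin-Wu-Hausman endogeneity test — compares OLS and TSLS via the
  control-function regression (first-stage residuals added to the
  structural OLS fit).  The Wu-Hausman F is the squared t-statistic on
  the control function; the Durbin statistic is the score (chi-square)
  form of the same contrast.  Both are reported; the F form is the
  headline p-value.
* Covariate balance screen — per-allele associations of each genotype
  with measured potential confounders (linear for continuous, logistic
  odds ratio for binary, chi-square across genotype classes for
  categorical), analogous to a baseline-characteristics table in a
  randomised trial.  P-values are reported raw, without multiplicity
  correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortData
from .tsls import IVModelSpec, RankDeficientError, Z95, _complete_rows, ols_arrays, tsls_arrays

__all__ = [
    "SarganResult",
    "HausmanResult",
    "sargan_test",
    "dwh_endogeneity_test",
    "covariate_balance_screen",
]


@dataclass(frozen=True)
class SarganResult:
    statistic: float | None
    df: int | None
    p: float | None
    applicable: bool = True
    reason: str | None = None


@dataclass(frozen=True)
class HausmanResult:
    wu_hausman_F: float
    wu_hausman_df: tuple[int, int]
    wu_hausman_p: float
    durbin_chi2: float
    durbin_df: int
    durbin_p: float

    @property
    def p(self) -> float:
        """Headline p-value (Wu-Hausman F form)."""
        return self.wu_hausman_p


def _extract(data: CohortData, spec: IVModelSpec):
    used = [spec.outcome, spec.exposure, *spec.instruments, *spec.covariates]
    sub = _complete_rows(data, used)
    y = sub.frame[spec.outcome].to_numpy(float)
    x = sub.frame[spec.exposure].to_numpy(float)
    Z = np.column_stack([sub.frame[c].to_numpy(float) for c in spec.instruments])
    W = (np.column_stack([sub.frame[c].to_numpy(float) for c in spec.covariates])
         if spec.covariates else None)
    return y, x, Z, W


def sargan_test(data: CohortData, spec: IVModelSpec) -> SarganResult:
    """Sargan test of over-identification (n.R^2 on chi-square L-1 df).

    For a just-identified model (single instrument) the test does not
    exist and an explicit not-applicable result is returned, matching
    the NA entries conventional in single-SNP report tables.
    """
    if spec.L < 2:
        return SarganResult(None, None, None, applicable=False,
                            reason="just-identified model (single instrument)")
    y, x, Z, W = _extract(data, spec)
    res = tsls_arrays(y, x, Z, W, spec.intercept, check_rank=True)
    u = res["residuals"]
    n = res["n"]
    parts = [np.ones(n)] if spec.intercept else []
    if W is not None:
        parts.append(W)
    parts.append(Z)
    A = np.column_stack(parts)
    coef, _, _ = ols_arrays(u, A)
    fitted = A @ coef
    uc = u - u.mean() if spec.intercept else u
    tss = float(uc @ uc)
    rss = float(((u - fitted) ** 2).sum())
    r2 = max(0.0, 1.0 - rss / tss)
    stat = n * r2
    df = spec.L - 1
    return SarganResult(float(stat), df, float(stats.chi2.sf(stat, df)))


def dwh_endogeneity_test(data: CohortData, spec: IVModelSpec) -> HausmanResult:
    """Durbin-Wu-Hausman test of exposure endogeneity (control-function form).

    Augments the structural OLS regression with the first-stage
    residuals v = x - x_hat; a non-zero coefficient on v indicates that
    OLS and TSLS estimands differ (unmeasured confounding of exposure
    and outcome).
    """
    y, x, Z, W = _extract(data, spec)
    res = tsls_arrays(y, x, Z, W, spec.intercept, check_rank=True)
    v = res["fs_resid"]
    n = res["n"]
    if float(v @ v) <= 1e-12 * float(x @ x):
        raise ValueError("exposure is an exact linear function of the instruments; "
                         "control function degenerate")
    parts = [np.ones(n)] if spec.intercept else []
    if W is not None:
        parts.append(W)
    X_r = np.column_stack(parts + [x])          # restricted: structural OLS
    X_u = np.column_stack(parts + [x, v])       # unrestricted: + control function
    _, _, e_r = ols_arrays(y, X_r)
    params_u, se_u, e_u = ols_arrays(y, X_u)
    rss_r = float(e_r @ e_r)
    rss_u = float(e_u @ e_u)
    p_u = X_u.shape[1]
    F = ((rss_r - rss_u) / 1.0) / (rss_u / (n - p_u))
    F = max(F, 0.0)
    durbin = n * (rss_r - rss_u) / rss_r
    durbin = max(durbin, 0.0)
    return HausmanResult(
        wu_hausman_F=float(F), wu_hausman_df=(1, n - p_u),
        wu_hausman_p=float(stats.f.sf(F, 1, n - p_u)),
        durbin_chi2=float(durbin), durbin_df=1,
        durbin_p=float(stats.chi2.sf(durbin, 1)),
    )


def covariate_balance_screen(data: CohortData, genotype_cols=None,
                             covariate_types: dict | None = None) -> pd.DataFrame:
    """Screen genotypes against measured potential confounders.

    ``covariate_types`` maps covariate column -> 'continuous', 'binary'
    or 'categorical'.  Continuous covariates get a per-allele linear
    regression coefficient, binary get a per-allele odds ratio from a
    logistic fit (both additive coding, with 95% CI and p), and
    categorical get a chi-square test across genotype classes.  Returns
    one row per (genotype, covariate) pair.
    """
    import statsmodels.api as sm

    genotype_cols = list(genotype_cols or data.genotypes)
    if covariate_types is None:
        covariate_types = {c: "continuous" for c in data.covariates}

    rows = []
    for g in genotype_cols:
        gvals = data.frame[g]
        if gvals.dropna().nunique() < 2:
            raise ValueError(f"genotype {g!r} is monomorphic in this sample")
        for cov, kind in covariate_types.items():
            pair = data.frame[[g, cov]].dropna()
            gv = pair[g].to_numpy(float)
            cv = pair[cov]
            row = {"genotype": g, "covariate": cov, "type": kind, "n": len(pair)}
            if kind == "continuous":
                if cv.nunique() < 2:
                    raise ValueError(f"covariate {cov!r} is constant")
                X = sm.add_constant(gv)
                fit = sm.OLS(cv.to_numpy(float), X).fit()
                b, s = fit.params[1], fit.bse[1]
                row.update(estimate=b, ci_low=b - Z95 * s, ci_high=b + Z95 * s,
                           p=float(fit.pvalues[1]))
            elif kind == "binary":
                vals = cv.to_numpy(float)
                if set(np.unique(vals)) - {0.0, 1.0}:
                    raise ValueError(f"binary covariate {cov!r} must be coded 0/1")
                X = sm.add_constant(gv)
                fit = sm.Logit(vals, X).fit(disp=0)
                b, s = fit.params[1], fit.bse[1]
                row.update(estimate=float(np.exp(b)),
                           ci_low=float(np.exp(b - Z95 * s)),
                           ci_high=float(np.exp(b + Z95 * s)),
                           p=float(fit.pvalues[1]))
            elif kind == "categorical":
                table = pd.crosstab(cv, pair[g])
                chi2, p, dof, _ = stats.chi2_contingency(table)
                row.update(estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
                           p=float(p), chi2=float(chi2), chi2_df=int(dof))
            else:
                raise ValueError(f"unknown covariate type {kind!r} for {cov!r}")
            rows.append(row)
    return pd.DataFrame(rows)
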