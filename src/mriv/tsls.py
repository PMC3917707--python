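"""OLS and two-stage least squares (TSLS) estimation for Mendelian randomisation.

The causal effect of an exposure X on an outcome Y is estimated with
genetic instruments G1..GL by TSLS: the exposure is projected onto the
instruments (plus exogenous covariates and an intercept) in a first
stage, and the outcome is regressed on the projection in the second
stage.  Standard errors are the classical homoskedastic TSLS standard
errors, computed from residuals at the *original* exposure (never the
fitted exposure), with the error variance estimated as RSS/n and normal
(1.96) confidence intervals — the conventions of the standard
econometric IV software this mirrors.

First-stage instrument strength is summarised by the excluded-instrument
R^2 and F statistic (partial versions when covariates are present);
F = [R^2/(1-R^2)] * [(n-k-1)/k] links the two when there are no
covariates, and 1/F approximates the relative bias of TSLS toward OLS
under weak instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CohortData

__all__ = [
    "IVModelSpec",
    "OLSFit",
    "TSLSFit",
    "FirstStageStats",
    "RankDeficientError",
    "fit_ols",
    "fit_tsls",
    "first_stage_stats",
    "f_from_r2",
    "relative_bias_approx",
    "report_geometric_ratio",
]

Z95 = 1.959963984540054  # normal 97.5% point


class RankDeficientError(np.linalg.LinAlgError):
    """Design or instrument matrix is rank deficient."""


@dataclass(frozen=True)
class IVModelSpec:
    """Specification of a single-exposure IV model.

    ``instruments`` are the excluded instruments (L >= 1 genotype or
    score columns); ``covariates`` are included exogenous regressors.
    """

    outcome: str
    exposure: str
    instruments: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "instruments", tuple(self.instruments))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if len(self.instruments) < 1:
            raise ValueError("at least one instrument required")
        if self.exposure in self.instruments:
            raise ValueError("exposure cannot be its own instrument")
        if set(self.instruments) & set(self.covariates):
            raise ValueError("instruments and covariates must be disjoint")

    @property
    def L(self) -> int:
        return len(self.instruments)


@dataclass(frozen=True)
class FirstStageStats:
    """Strength of the excluded instruments in the first-stage regression."""

    r2: float
    F: float
    k: int
    n: int
    coefficients: dict = field(default_factory=dict)  # name -> (beta, lo, hi)
    partial: bool = False
    warning: str | None = None


@dataclass(frozen=True)
class OLSFit:
    beta_hat: float
    se: float
    ci_95: tuple[float, float]
    n: int
    params: np.ndarray
    residuals: np.ndarray
    outcome_log_scale: bool = False


@dataclass(frozen=True)
class TSLSFit:
    beta_hat: float
    se: float
    ci_95: tuple[float, float]
    n: int
    L: int
    params: np.ndarray
    residuals: np.ndarray
    first_stage: FirstStageStats
    outcome_log_scale: bool = False


def _check_rank(A: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise RankDeficientError(f"{what} matrix is rank deficient")


def _design(data: CohortData, columns, intercept: bool) -> np.ndarray:
    cols = [data.frame[c].to_numpy(float) for c in columns]
    if intercept:
        cols.insert(0, np.ones(data.n))
    return np.column_stack(cols) if cols else np.empty((data.n, 0))


def _complete_rows(data: CohortData, columns) -> CohortData:
    from dataclasses import replace

    ok = data.frame[list(columns)].notna().all(axis=1)
    if ok.all():
        return data
    return replace(data, frame=data.frame.loc[ok])


def ols_arrays(y: np.ndarray, X: np.ndarray):
    """Classical OLS: returns (params, se vector, residuals); sigma^2 = RSS/(n-p)."""
    n, p = X.shape
    XtX = X.T @ X
    try:
        params = np.linalg.solve(XtX, X.T @ y)
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError(str(exc)) from exc
    resid = y - X @ params
    sigma2 = float(resid @ resid) / max(n - p, 1)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    return params, se, resid


def tsls_arrays(y: np.ndarray, x: np.ndarray, Z: np.ndarray,
                W: np.ndarray | None = None, intercept: bool = True,
                check_rank: bool = False) -> dict:
    """TSLS on raw arrays; shared by the public fit and the Monte Carlo engine.

    y: outcome (n,); x: endogenous exposure (n,); Z: excluded instruments
    (n, k); W: exogenous covariates (n, q) or None.  Returns a dict with
    the causal estimate, its SE, full second-stage parameters, residuals
    and the first-stage summary (partial R^2/F when W is present).
    """
    n = len(y)
    if Z.ndim == 1:
        Z = Z[:, None]
    k = Z.shape[1]
    if W is not None and not W.size:
        W = None

    # With an intercept, work with mean-centred variables (Frisch-Waugh):
    # slope estimates, their covariance block and all residuals are
    # unchanged, and the conditioning of the normal equations improves.
    if intercept:
        ymean, xmean = y.mean(), x.mean()
        Zmean = Z.mean(axis=0)
        yw, xw, Zw = y - ymean, x - xmean, Z - Zmean
        Wmean = W.mean(axis=0) if W is not None else None
        Ww = W - Wmean if W is not None else None
    else:
        yw, xw, Zw, Ww = y, x, Z, W
    C = Ww if Ww is not None else np.empty((n, 0))
    A = np.column_stack([C, Zw]) if C.size else Zw  # excluded + included exog (sans intercept)
    q = C.shape[1] + (1 if intercept else 0)        # exogenous regressor count
    if n <= A.shape[1] + (1 if intercept else 0) + 1:
        raise ValueError("too few observations for the number of instruments/covariates")
    if check_rank:
        _check_rank(A, "instrument")

    AtA = A.T @ A
    try:
        gamma = np.linalg.solve(AtA, A.T @ xw)  # first-stage coefficients (slopes)
        AtA_inv = np.linalg.inv(AtA)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError(str(exc)) from exc
    xhat = A @ gamma
    fs_resid = xw - xhat
    ssr = float(fs_resid @ fs_resid)

    # second stage: regress y on [C, x] with x replaced by its projection
    Xf = np.column_stack([C, xw]) if C.size else xw[:, None]
    Xp = np.column_stack([C, xhat]) if C.size else xhat[:, None]
    M = Xp.T @ Xp  # equals Xf' P Xf since C lies in the span of the instruments
    try:
        slopes = np.linalg.solve(M, Xp.T @ yw)
        M_inv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError(str(exc)) from exc
    resid = yw - Xf @ slopes  # residuals at the ORIGINAL exposure
    sigma2 = float(resid @ resid) / n
    se_all = np.sqrt(np.maximum(sigma2 * np.diag(M_inv), 0.0))
    if intercept:
        drift = float(Wmean @ slopes[:-1]) if W is not None else 0.0
        params = np.concatenate([[ymean - drift - xmean * slopes[-1]], slopes])
    else:
        params = slopes

    # first-stage strength of the excluded instruments
    if C.size:
        # partial R^2/F: variation in x left after the included exogenous regressors
        cc = np.linalg.lstsq(C, xw, rcond=None)[0]
        x_part = xw - C @ cc
        tss = float(x_part @ x_part)
    else:
        tss = float(xw @ xw)
    if tss <= 0:
        raise ValueError("exposure has zero variance after partialling")
    r2 = max(0.0, 1.0 - ssr / tss)
    df_denom = n - k - q
    # r2 = 1 (instruments span the exposure exactly) leaves TSLS well defined
    # and equal to OLS; only the F-statistic degenerates
    F = np.inf if r2 >= 1.0 else (r2 / (1.0 - r2)) * (df_denom / k)

    # per-instrument first-stage coefficients with normal 95% CIs
    fs_sigma2 = ssr / max(n - k - q, 1)
    fs_se = np.sqrt(np.maximum(fs_sigma2 * np.diag(AtA_inv), 0.0))
    fs_coefs = {}
    off = C.shape[1]
    for j in range(k):
        b, s = gamma[off + j], fs_se[off + j]
        fs_coefs[j] = (float(b), float(b - Z95 * s), float(b + Z95 * s))

    return {
        "beta_hat": float(slopes[-1]),
        "se": float(se_all[-1]),
        "params": params,
        "residuals": resid,
        "r2": float(r2),
        "F": float(F),
        "k": k,
        "n": n,
        "q_exog": q,
        "fs_coefs": fs_coefs,
        "partial": W is not None and W.size > 0,
        "xhat": xhat,
        "fs_resid": fs_resid,
    }


def fit_ols(data: CohortData, outcome: str | None = None, exposure: str | None = None,
            covariates=None, intercept: bool = True) -> OLSFit:
    """OLS of the outcome on the exposure (plus covariates), classical SEs."""
    outcome = outcome or data.outcome
    exposure = exposure or data.exposure
    covariates = list(data.covariates if covariates is None else covariates)
    sub = _complete_rows(data, [outcome, exposure, *covariates])
    y = sub.frame[outcome].to_numpy(float)
    X = _design(sub, [*covariates, exposure], intercept)
    _check_rank(X, "design")
    params, se, resid = ols_arrays(y, X)
    b, s = float(params[-1]), float(se[-1])
    return OLSFit(b, s, (b - Z95 * s, b + Z95 * s), len(y), params, resid,
                  outcome_log_scale=data.outcome_is_log_scale())


def fit_tsls(data: CohortData, spec: IVModelSpec) -> TSLSFit:
    """Two-stage least squares estimate of the causal effect of the exposure.

    Rows missing any used column are dropped (per-model complete case);
    apply a :class:`~mriv.data.MissingnessPolicy` first for a common
    analysis sample across models.
    """
    used = [spec.outcome, spec.exposure, *spec.instruments, *spec.covariates]
    sub = _complete_rows(data, used)
    y = sub.frame[spec.outcome].to_numpy(float)
    x = sub.frame[spec.exposure].to_numpy(float)
    Z = np.column_stack([sub.frame[c].to_numpy(float) for c in spec.instruments])
    W = (np.column_stack([sub.frame[c].to_numpy(float) for c in spec.covariates])
         if spec.covariates else None)
    res = tsls_arrays(y, x, Z, W, spec.intercept, check_rank=True)
    fs = FirstStageStats(
        r2=res["r2"], F=res["F"], k=res["k"], n=res["n"],
        coefficients={name: res["fs_coefs"][j] for j, name in enumerate(spec.instruments)},
        partial=bool(spec.covariates),
    )
    b, s = res["beta_hat"], res["se"]
    return TSLSFit(b, s, (b - Z95 * s, b + Z95 * s), res["n"], spec.L,
                   res["params"], res["residuals"], fs,
                   outcome_log_scale=data.outcome_is_log_scale())


def first_stage_stats(data: CohortData, spec: IVModelSpec) -> FirstStageStats:
    """First-stage instrument strength (partial R^2/F when covariates present)."""
    return fit_tsls(data, spec).first_stage


def f_from_r2(r2: float, n: int, k: int) -> float:
    """F implied by the first-stage R^2: F = [r2/(1-r2)] * [(n-k-1)/k].

    Valid for a model with intercept and no covariates, where k is the
    number of instruments.
    """
    if not 0 <= r2 < 1:
        if r2 == 1:
            raise ValueError("r2 = 1 implies an infinite F-statistic")
        raise ValueError("r2 must lie in [0, 1)")
    if k < 1 or n <= k + 1:
        raise ValueError("need k >= 1 and n > k + 1")
    return (r2 / (1.0 - r2)) * ((n - k - 1) / k)


def relative_bias_approx(F: float) -> dict:
    """Approximate relative bias of TSLS toward OLS: 1/F.

    A first-stage F of 10 corresponds to roughly 10% relative bias,
    which is the origin of the F > 10 weak-instrument rule of thumb.
    Returns both the proportion and the percentage.
    """
    if F <= 0:
        raise ValueError("F must be positive")
    return {"proportion": 1.0 / F, "percent": 100.0 / F}


def report_geometric_ratio(fit: OLSFit | TSLSFit) -> dict:
    """Exponentiate a log-scale estimate into a ratio of geometric means.

    Only meaningful when the outcome was log transformed; the fit must
    carry that metadata.  CI endpoints are the exponentiated log-scale
    endpoints, so the interval brackets the ratio.
    """
    if not fit.outcome_log_scale:
        raise ValueError("outcome is not on the log scale; ratio of geometric means undefined")
    lo, hi = fit.ci_95
    return {"ratio": float(np.exp(fit.beta_hat)), "ci": (float(np.exp(lo)), float(np.exp(hi)))}
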