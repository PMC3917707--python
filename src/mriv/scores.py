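"""Allele scores: collapsing several genotypes into one composite instrument.

An allele score sums risk-allele counts across SNPs, optionally weighted
by each SNP's effect on the exposure.  Using the score as a single
instrument raises the first-stage F (one numerator degree of freedom)
at equal R^2; with internally estimated weights that single degree of
freedom flatters the F, which is surfaced as a warning.

Weighting modes:

* unweighted — score_i = sum_j G_ij (integer in [0, 2L]);
* internal  — w_j from the univariable regression of the exposure on
  each genotype in the analysis sample, score_i = sum_j w_j G_ij / sum_j w_j;
* external  — caller-supplied weights (e.g. from an independent GWAS),
  same normalisation.

Missing genotypes propagate strictly: a row missing any constituent SNP
has a missing score (mean-imputation of dosages is available behind a
flag, off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlleleScore",
    "unweighted_score",
    "weighted_score_internal",
    "weighted_score_external",
    "read_weights",
    "write_weights",
    "INTERNAL_WEIGHT_F_CAVEAT",
]

INTERNAL_WEIGHT_F_CAVEAT = (
    "score weights were estimated from the analysis sample; the single-df "
    "first-stage F-statistic may overstate instrument strength"
)


@dataclass(frozen=True)
class AlleleScore:
    """Per-individual score values plus the weights and their provenance."""

    values: pd.Series
    weights: dict
    mode: str  # unweighted | internal | external
    sum_weights: float
    weight_regressions: dict = field(default_factory=dict)  # internal mode bookkeeping

    @property
    def f_statistic_caveat(self) -> str | None:
        return INTERNAL_WEIGHT_F_CAVEAT if self.mode == "internal" else None


def _as_frame(G) -> pd.DataFrame:
    if isinstance(G, pd.DataFrame):
        return G
    G = np.asarray(G, float)
    return pd.DataFrame(G, columns=[f"G{j + 1}" for j in range(G.shape[1])])


def _combine(G: pd.DataFrame, w: np.ndarray, impute_missing: bool) -> pd.Series:
    mat = G.to_numpy(float)
    if impute_missing:
        means = np.nanmean(mat, axis=0)
        mat = np.where(np.isnan(mat), means, mat)
    vals = mat @ w
    vals[np.isnan(mat).any(axis=1)] = np.nan
    return pd.Series(vals, index=G.index, name="score")


def unweighted_score(G, *, impute_missing: bool = False) -> AlleleScore:
    """Unweighted allele score: sum of effect-allele counts across SNPs."""
    G = _as_frame(G)
    if G.shape[1] == 0:
        raise ValueError("empty SNP set")
    w = np.ones(G.shape[1])
    values = _combine(G, w, impute_missing)
    return AlleleScore(values, {c: 1.0 for c in G.columns}, "unweighted", float(G.shape[1]))


def weighted_score_internal(G, exposure, *, joint: bool = False,
                            impute_missing: bool = False) -> AlleleScore:
    """Allele score weighted by in-sample genotype-exposure regressions.

    Each weight is the slope of the univariable regression (with
    intercept) of the exposure on that genotype, estimated on rows where
    both are observed; the score is the weighted dosage sum divided by
    the sum of weights.  With ``joint=True`` the weights are instead the
    coefficients of the joint first-stage regression on all SNPs, which
    makes score-based TSLS coincide exactly with multi-instrument TSLS
    in-sample.
    """
    G = _as_frame(G)
    if G.shape[1] == 0:
        raise ValueError("empty SNP set")
    x = np.asarray(exposure, float)
    if len(x) != len(G):
        raise ValueError("exposure length does not match genotype matrix")

    regressions: dict = {}
    if joint:
        ok = ~np.isnan(x) & G.notna().all(axis=1).to_numpy()
        A = np.column_stack([np.ones(ok.sum()), G.to_numpy(float)[ok]])
        coef, *_ = np.linalg.lstsq(A, x[ok], rcond=None)
        w = coef[1:]
        regressions = {c: {"kind": "joint_first_stage", "n": int(ok.sum())} for c in G.columns}
    else:
        w = np.empty(G.shape[1])
        for j, c in enumerate(G.columns):
            g = G[c].to_numpy(float)
            ok = ~np.isnan(g) & ~np.isnan(x)
            gv = g[ok]
            if np.ptp(gv) == 0:
                raise ValueError(f"SNP {c!r} is monomorphic; weight undefined")
            gc = gv - gv.mean()
            w[j] = float(gc @ (x[ok] - x[ok].mean()) / (gc @ gc))
            regressions[c] = {"kind": "univariable", "n": int(ok.sum())}
    sw = float(w.sum())
    if abs(sw) < 1e-12:
        raise ValueError("sum of estimated weights is zero; weighted score undefined")
    values = _combine(G, w / sw, impute_missing)
    return AlleleScore(values, dict(zip(G.columns, map(float, w))), "internal", sw, regressions)


def weighted_score_external(G, weights, *, impute_missing: bool = False) -> AlleleScore:
    """Allele score with externally supplied per-SNP weights."""
    G = _as_frame(G)
    if G.shape[1] == 0:
        raise ValueError("empty SNP set")
    if isinstance(weights, dict):
        missing = [c for c in G.columns if c not in weights]
        if missing:
            raise ValueError(f"no weight supplied for SNPs: {missing}")
        w = np.array([float(weights[c]) for c in G.columns])
    else:
        w = np.asarray(weights, float)
        if w.shape != (G.shape[1],):
            raise ValueError(f"expected {G.shape[1]} weights, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    sw = float(w.sum())
    if abs(sw) < 1e-12:
        raise ValueError("weights sum to zero; normalised score undefined")
    values = _combine(G, w / sw, impute_missing)
    return AlleleScore(values, dict(zip(G.columns, map(float, w))), "external", sw)


def read_weights(path) -> dict:
    """Read per-SNP weights from a two-column CSV (snp_id, weight)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("weights file needs two columns: snp_id, weight")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_weights(weights: dict, path) -> None:
    pd.DataFrame({"snp_id": list(weights), "weight": [weights[k] for k in weights]}).to_csv(
        path, index=False)
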