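"""Cohort data handling for Mendelian randomisation analyses.

Individual-level data are held in a :class:`CohortData`: one row per
participant, with an outcome, an exposure (the modifiable risk factor),
optional exogenous covariates, and genotype columns coded additively as
0/1/2 counts of a declared effect allele.  Missing genotypes are kept as
NaN and never silently dropped; which rows enter an analysis is decided
by an explicit :class:`MissingnessPolicy`.

The module also provides Hardy-Weinberg equilibrium testing, trait
standardisation (log transform plus age/sex-adjusted z-scoring), VCF
dosage extraction, and a synthetic-cohort generator that emulates the
structure of a genotyped birth-cohort study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CohortData",
    "GenotypeCounts",
    "HWEResult",
    "MissingnessPolicy",
    "FixtureConfig",
    "SchemaError",
    "read_cohort_table",
    "write_cohort_table",
    "load_schema",
    "vcf_to_dosage",
    "hwe_chisq",
    "genotype_counts",
    "standardize_trait",
    "apply_missingness_policy",
    "generate_fixture",
]

DEFAULT_MISSING_CODES = ("", "NA", "NaN", ".", "./.", ".|.")


class SchemaError(ValueError):
    """Raised when a cohort table does not match its declared schema."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts (0/1/2 copies of the effect allele) for one biallelic SNP."""

    n0: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if min(self.n0, self.n1, self.n2) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def allele_frequency(self) -> float:
        """Sample frequency of the allele counted by the dosage coding."""
        return (self.n1 + 2 * self.n2) / (2 * self.n)

    def flipped(self) -> "GenotypeCounts":
        return GenotypeCounts(self.n2, self.n1, self.n0)


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p: float
    monomorphic: bool = False


@dataclass(frozen=True)
class MissingnessPolicy:
    """How missing genotypes determine the analysis sample.

    ``complete_case_all_instruments`` restricts to rows complete on every
    listed instrument (plus outcome, exposure and covariates) so that all
    models run on one common sample; ``complete_case_per_model`` defers
    filtering to each fitted model, using the maximum available N per
    analysis.
    """

    mode: str = "complete_case_all_instruments"

    _MODES = ("complete_case_all_instruments", "complete_case_per_model")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown policy mode {self.mode!r}; choose from {self._MODES}")


@dataclass
class CohortData:
    """Rectangular individual-level dataset for an IV analysis.

    frame
        One row per individual.  Genotype columns are float dosages in
        {0, 1, 2} with NaN for missing.
    outcome, exposure
        Column names of the outcome and the (endogenous) exposure.
    covariates, genotypes
        Column names of exogenous covariates and genotype dosages.
    transforms
        Per-column record of transformations already applied (e.g.
        ``{"bmd": "log+zscore"}``); guards against double application and
        lets downstream reports know whether exponentiation to a ratio of
        geometric means is meaningful.
    """

    frame: pd.DataFrame
    outcome: str
    exposure: str
    covariates: list[str] = field(default_factory=list)
    genotypes: list[str] = field(default_factory=list)
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in [self.outcome, self.exposure, *self.covariates, *self.genotypes]:
            if col not in self.frame.columns:
                raise SchemaError(f"column {col!r} not present in cohort table")
        g = self.frame[self.genotypes].to_numpy(float) if self.genotypes else np.empty((len(self.frame), 0))
        bad = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"genotype column {self.genotypes[j]!r} row {self.frame.index[i]} has "
                f"dosage {g[i, j]!r} outside {{0,1,2}}"
            )

    @property
    def n(self) -> int:
        return len(self.frame)

    def genotype_matrix(self) -> np.ndarray:
        return self.frame[self.genotypes].to_numpy(float)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask (True = missing) over genotype columns."""
        return self.frame[self.genotypes].isna()

    def outcome_is_log_scale(self) -> bool:
        return "log" in self.transforms.get(self.outcome, "")


def load_schema(path) -> dict:
    """Load a column-role schema from YAML or JSON.

    Expected keys: ``outcome``, ``exposure``, optional ``covariates``
    (list), ``genotypes`` (mapping column -> {``effect_allele``: str} or
    null for pre-coded 0/1/2 dosages), optional ``missing_codes`` and
    ``id``.
    """
    with open(path) as fh:
        text = fh.read()
    schema = yaml.safe_load(text)
    if not isinstance(schema, dict) or "outcome" not in schema or "exposure" not in schema:
        raise SchemaError("schema must be a mapping with at least 'outcome' and 'exposure'")
    return schema


def _parse_genotype_column(values: pd.Series, column: str, effect_allele: str | None,
                           missing_codes: tuple[str, ...]) -> np.ndarray:
    out = np.full(len(values), np.nan)
    for i, raw in enumerate(values.astype(object)):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        s = str(raw).strip()
        if s in missing_codes:
            continue
        try:
            d = float(s)
        except ValueError:
            # allele-pair string such as "TA", "T/A" or "T|A"
            if effect_allele is None:
                raise SchemaError(
                    f"column {column!r} row {values.index[i]}: allele pair {s!r} given "
                    "but no effect allele declared in the schema"
                )
            alleles = [a for a in s.replace("/", "").replace("|", "")]
            if len(alleles) != 2:
                raise SchemaError(f"column {column!r} row {values.index[i]}: cannot parse genotype {s!r}")
            out[i] = sum(a == effect_allele for a in alleles)
            if out[i] == 0 and effect_allele not in alleles:
                # legitimate: homozygous other allele; but flag foreign alphabets
                known = set(alleles) | {effect_allele}
                if not known <= set("ACGT"):
                    raise SchemaError(f"column {column!r} row {values.index[i]}: unknown allele in {s!r}")
            continue
        if d not in (0.0, 1.0, 2.0):
            raise SchemaError(
                f"column {column!r} row {values.index[i]}: dosage {s!r} outside {{0,1,2}}"
            )
        out[i] = d
    return out


def read_cohort_table(path, schema: dict | str, *, sep: str = ",") -> CohortData:
    """Read a delimited cohort table into a :class:`CohortData`.

    ``schema`` is a mapping (or path to a YAML/JSON file) assigning roles
    to columns; genotype columns may hold 0/1/2 dosages or allele-pair
    strings resolved against a declared effect allele.  Missing entries
    are flagged as NaN; the row count of the file is preserved.
    """
    if not isinstance(schema, dict):
        schema = load_schema(schema)
    missing_codes = tuple(schema.get("missing_codes", DEFAULT_MISSING_CODES))
    raw = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)

    genos = schema.get("genotypes", {}) or {}
    covars = list(schema.get("covariates", []) or [])
    for col in [schema["outcome"], schema["exposure"], *covars, *genos]:
        if col not in raw.columns:
            raise SchemaError(f"schema column {col!r} not found in {path}")

    frame = pd.DataFrame(index=raw.index)
    if schema.get("id") and schema["id"] in raw.columns:
        frame[schema["id"]] = raw[schema["id"]]
    for col in [schema["outcome"], schema["exposure"], *covars]:
        vals = raw[col].replace(list(missing_codes), np.nan)
        try:
            frame[col] = pd.to_numeric(vals)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric value in column {col!r}: {exc}") from exc
    for col, info in genos.items():
        allele = (info or {}).get("effect_allele") if isinstance(info, dict) else info
        frame[col] = _parse_genotype_column(raw[col], col, allele, missing_codes)
    # carry remaining columns through (numeric where possible) so callers can
    # screen or adjust on variables outside the declared roles
    for col in raw.columns:
        if col not in frame.columns:
            vals = raw[col].replace(list(missing_codes), np.nan)
            try:
                frame[col] = pd.to_numeric(vals)
            except (ValueError, TypeError):
                frame[col] = vals

    return CohortData(
        frame=frame,
        outcome=schema["outcome"],
        exposure=schema["exposure"],
        covariates=covars,
        genotypes=list(genos),
        transforms=dict(schema.get("transforms", {})),
    )


def write_cohort_table(data: CohortData, path, *, missing_code: str = "NA") -> None:
    """Write a cohort table as CSV with dosage-coded genotypes.

    Round-trips through :func:`read_cohort_table` with a numeric-dosage
    schema (genotype columns mapped to ``null``).
    """
    out = data.frame.copy()
    for col in data.genotypes:
        out[col] = out[col].map(lambda v: missing_code if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, na_rep=missing_code)


def vcf_to_dosage(path, variant_ids: list[str], effect_alleles: dict[str, str]):
    """Extract additive dosages for the requested variants from a VCF.

    Returns ``(dosage DataFrame [samples x variants], sample ids)``.  The
    dosage is the per-sample count of the declared effect allele; missing
    genotypes (``./.``) become NaN.  Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    found: dict[str, np.ndarray] = {}
    wanted = set(variant_ids)
    for rec in vcf:
        if rec.ID not in wanted:
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"variant {rec.ID} is multiallelic (ALT={rec.ALT}); only biallelic supported")
        allele = effect_alleles[rec.ID]
        if allele == rec.ALT[0]:
            flip = False
        elif allele == rec.REF:
            flip = True
        else:
            raise ValueError(
                f"effect allele {allele!r} for {rec.ID} is neither REF ({rec.REF}) nor ALT ({rec.ALT[0]})"
            )
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        found[rec.ID] = 2.0 - dos if flip else dos
    missing = wanted - set(found)
    if missing:
        raise ValueError(f"variants absent from VCF: {sorted(missing)}")
    mat = pd.DataFrame({vid: found[vid] for vid in variant_ids}, index=samples)
    return mat, samples


def genotype_counts(dosages) -> GenotypeCounts:
    """Tally 0/1/2 genotype classes from a dosage vector, ignoring missing."""
    d = np.asarray(dosages, float)
    d = d[~np.isnan(d)]
    return GenotypeCounts(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def hwe_chisq(counts: GenotypeCounts) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df).

    Expected genotype frequencies (1-q)^2 : 2q(1-q) : q^2 are computed
    from the sample allele frequency q.  A monomorphic variant (q = 0 or
    1) fits HWE trivially and returns chi2=0, p=1 with a warning flag.
    """
    if counts.n == 0:
        raise ValueError("no genotyped individuals")
    q = counts.allele_frequency
    if q in (0.0, 1.0):
        return HWEResult(0.0, 1, 1.0, monomorphic=True)
    expected = counts.n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    observed = np.array([counts.n0, counts.n1, counts.n2], float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(chi2, 1, float(stats.chi2.sf(chi2, 1)))


def standardize_trait(values, *, log_first: bool = False, age=None, sex=None) -> np.ndarray:
    """Standardise a trait to an (optionally age/sex-adjusted) z-score.

    With ``log_first`` the trait is log-transformed (all non-missing
    values must be positive).  If ``age``/``sex`` are supplied the
    (log) values are linearly adjusted for them and the residuals are
    scaled to unit SD; otherwise a plain z-score is returned.  Missing
    entries stay missing.
    """
    v = np.asarray(values, float).copy()
    ok = ~np.isnan(v)
    if log_first:
        if np.any(v[ok] <= 0):
            raise ValueError("log transform requested but non-positive values present")
        v[ok] = np.log(v[ok])
    cols = [np.ones(ok.sum())]
    for c in (age, sex):
        if c is not None:
            c = np.asarray(c, float)
            if np.isnan(c[ok]).any():
                raise ValueError("adjustment covariate missing where trait is observed")
            cols.append(c[ok])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
    resid = v[ok] - X @ beta
    sd = resid.std(ddof=0)
    if sd == 0:
        raise ValueError("zero residual variance; trait cannot be standardised")
    out = np.full_like(v, np.nan)
    out[ok] = resid / sd
    return out


def apply_missingness_policy(data: CohortData, policy: MissingnessPolicy,
                             instruments: list[str]):
    """Resolve missing genotypes into an analysis dataset plus accounting.

    Returns ``(cohort, accounting)`` where ``accounting`` is a DataFrame
    reporting the genotyped N (and fraction of the cohort) per instrument
    and for the joint complete-case sample.  Under the all-instruments
    mode the returned cohort is restricted to rows complete on every
    listed instrument, the outcome, the exposure and the covariates;
    under the per-model mode the cohort is returned unchanged and each
    fit uses its own maximum available N.
    """
    if not instruments:
        raise ValueError("empty instrument set")
    unknown = [g for g in instruments if g not in data.genotypes]
    if unknown:
        raise ValueError(f"instruments not among genotype columns: {unknown}")

    base_cols = [data.outcome, data.exposure, *data.covariates]
    base_ok = data.frame[base_cols].notna().all(axis=1)
    rows = []
    for g in instruments:
        n_g = int((data.frame[g].notna() & base_ok).sum())
        rows.append({"column": g, "n": n_g, "fraction": n_g / data.n})
    complete = base_ok & data.frame[instruments].notna().all(axis=1)
    n_all = int(complete.sum())
    rows.append({"column": "all_instruments", "n": n_all, "fraction": n_all / data.n})
    accounting = pd.DataFrame(rows)

    if policy.mode == "complete_case_all_instruments":
        if n_all == 0:
            raise ValueError("no rows complete on all instruments")
        subset = replace(data, frame=data.frame.loc[complete].copy())
        return subset, accounting
    return data, accounting


# ---------------------------------------------------------------------------
# Synthetic cohort generation

@dataclass(frozen=True)
class FixtureConfig:
    """Specification for a synthetic genotyped cohort.

    Defaults emulate a childhood birth-cohort adiposity/bone-density
    study: four biallelic SNPs in HWE with realistic effect-allele
    frequencies, small additive per-allele effects on the log exposure,
    a shared latent confounder driving both traits, log-normal exposure
    and outcome, and per-SNP missingness in the 2-8% range so that the
    joint complete-case sample is noticeably smaller than any single-SNP
    sample.

    ``snps`` maps name -> (effect allele frequency, per-allele effect on
    the log exposure); ``missingness`` maps name -> missing fraction.
    ``causal_effect`` is the effect of log exposure on log outcome.
    """

    n: int = 5509
    snps: dict = field(default_factory=lambda: {
        "FTO": (0.396, 0.11),
        "MC4R": (0.238, 0.09),
        "TMEM18": (0.166, -0.06),
        "GNPDA2": (0.428, 0.05),
    })
    missingness: dict = field(default_factory=lambda: {
        "FTO": 0.076, "MC4R": 0.018, "TMEM18": 0.034, "GNPDA2": 0.037,
    })
    confounder_sd: float = 0.5
    causal_effect: float = 0.35
    exposure_noise_sd: float = 0.85
    outcome_noise_sd: float = 0.85

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name, (freq, _) in self.snps.items():
            if not 0 < freq < 1:
                raise ValueError(f"allele frequency for {name} must be in (0,1)")
        for name, rate in self.missingness.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missingness rate for {name} must be in [0,1)")


def generate_fixture(config: FixtureConfig | None = None, seed: int | None = 0) -> CohortData:
    """Generate a synthetic cohort table with the structure of a real study.

    Genotypes are Binomial(2, freq) draws (HWE by construction); the log
    exposure is the genetic signal plus a latent confounder U and noise;
    the log outcome is ``causal_effect``x(log exposure) plus the same U
    plus noise, so naive regression of outcome on exposure is confounded.
    Exposure and outcome are stored on the natural (log-normal) scale
    together with age, sex and height columns; missingness is injected
    per SNP independently.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(seed)
    n = config.n
    names = list(config.snps)
    freqs = np.array([config.snps[s][0] for s in names])
    effects = np.array([config.snps[s][1] for s in names])

    G = rng.binomial(2, freqs, size=(n, len(names))).astype(float)
    U = rng.normal(0.0, config.confounder_sd, n)
    zx = G @ effects + U + rng.normal(0.0, config.exposure_noise_sd, n)
    zy = config.causal_effect * zx + U + rng.normal(0.0, config.outcome_noise_sd, n)

    age = rng.normal(9.88, 0.32, n)
    sex = rng.binomial(1, 0.493, n).astype(float)
    height = rng.normal(139.6, 6.3, n) + 2.0 * (age - 9.88)
    # natural-scale traits: log-normal, with the log-exposure deviation zx
    # entering log outcome with slope `causal_effect` (so the log-log
    # regression slope adjusted for age/sex recovers it)
    fat_mass = np.exp(np.log(7209.0) + 0.08 * (age - 9.88) - 0.05 * sex + zx)
    bmd = np.exp(np.log(0.902) + 0.01 * (age - 9.88) + zy)

    frame = pd.DataFrame({
        "id": [f"ind{i:05d}" for i in range(n)],
        "bmd": bmd, "fat_mass": fat_mass,
        "age": age, "sex": sex, "height": height,
    })
    for j, name in enumerate(names):
        col = G[:, j].copy()
        rate = config.missingness.get(name, 0.0)
        if rate > 0:
            col[rng.random(n) < rate] = np.nan
        frame[name] = col

    return CohortData(
        frame=frame,
        outcome="bmd",
        exposure="fat_mass",
        covariates=["height"],
        genotypes=names,
        transforms={},
    )
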