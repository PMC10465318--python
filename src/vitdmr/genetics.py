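"""Polygenic score construction, SNP screening and instrument validation.

The instrument is an unweighted vitamin D polygenic score (VD-PGS): the sum
of 25(OH)D-lowering allele counts over the included SNPs.  Instrument
strength is summarised by the incremental R-squared of the PGS in a linear
model of 25(OH)D adjusted for age and sex, and by

    F = (N - 2) * R^2 / (1 - R^2),

with F > 10 the conventional adequacy threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import SchemaError
from .simulate import GENOTYPE_COLUMNS

DEFAULT_SNP_COLUMNS = GENOTYPE_COLUMNS
PGS_COLUMN = "pgs"


@dataclass
class PgsResult:
    """Per-participant unweighted polygenic score."""

    scores: pd.Series
    included_snps: list[str]
    excluded_snps: list[tuple[str, str]] = field(default_factory=list)

    @property
    def max_score(self) -> int:
        return 2 * len(self.included_snps)


@dataclass
class InstrumentFit:
    """PGS -> exposure association with strength diagnostics."""

    beta_gx: float
    se_gx: float
    p_gx: float
    r_squared: float
    f_statistic: float
    n: int

    def summary(self) -> str:
        return (
            "Instrument (VD-PGS -> 25(OH)D, adjusted for age and sex)\n"
            f"  beta = {self.beta_gx:+.4f} ng/mL per allele (SE {self.se_gx:.4f}, "
            f"p = {self.p_gx:.3g})\n"
            f"  incremental R^2 = {self.r_squared:.4f}   "
            f"F = {self.f_statistic:.2f}   N = {self.n}"
        )


def f_statistic(r_squared: float, n: int) -> float:
    """Instrument F-statistic, F = (N - 2) R^2 / (1 - R^2)."""
    if not (0.0 <= r_squared < 1.0):
        raise ValueError("r_squared must lie in [0, 1)")
    return (n - 2) * r_squared / (1.0 - r_squared)


def compute_pgs(cohort: pd.DataFrame, snp_columns=DEFAULT_SNP_COLUMNS) -> PgsResult:
    """Sum of lowering-allele counts; missing if any component is missing.

    Raises :class:`SchemaError` naming the first offending row if a
    genotype lies outside {0, 1, 2}.
    """
    snp_columns = list(snp_columns)
    for col in snp_columns:
        vals = cohort[col]
        bad = vals.notna() & ~vals.isin([0, 1, 2])
        if bad.any():
            row = bad[bad].index[0]
            raise SchemaError(
                f"genotype {col}={vals.loc[row]!r} at row {row} is outside {{0, 1, 2}}"
            )
    block = cohort[snp_columns]
    scores = block.sum(axis=1, min_count=len(snp_columns)).astype("Int64")
    scores.name = PGS_COLUMN
    return PgsResult(scores=scores, included_snps=snp_columns)


def add_pgs(cohort: pd.DataFrame, snp_columns=DEFAULT_SNP_COLUMNS) -> pd.DataFrame:
    """Copy of the cohort with a ``pgs`` column appended (or refreshed)."""
    out = cohort.copy()
    out[PGS_COLUMN] = compute_pgs(cohort, snp_columns).scores
    return out


def screen_snps(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    snp_columns=DEFAULT_SNP_COLUMNS,
    exposure: str = "vitd",
) -> pd.DataFrame:
    """Per-SNP association with the exposure, adjusted for age and sex.

    Returns a frame with columns snp, beta, se, p, kept, reason.  SNPs with
    p >= alpha are excluded; monomorphic SNPs are excluded with reason
    "no variation" rather than crashing the linear fit.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    rows = []
    for col in snp_columns:
        sub = cohort[[exposure, col, "age", "sex"]].dropna()
        g = sub[col].astype(float)
        if g.nunique() <= 1:
            rows.append({"snp": col, "beta": np.nan, "se": np.nan, "p": np.nan,
                         "kept": False, "reason": "no variation"})
            continue
        model = smf.ols(f"{exposure} ~ {col} + age + C(sex)",
                        data=sub.assign(**{col: g})).fit()
        p = float(model.pvalues[col])
        kept = p < alpha
        rows.append({
            "snp": col,
            "beta": float(model.params[col]),
            "se": float(model.bse[col]),
            "p": p,
            "kept": kept,
            "reason": "" if kept else f"p >= {alpha}",
        })
    return pd.DataFrame(rows)


def fit_instrument(
    cohort: pd.DataFrame,
    exposure: str = "vitd",
    covariates: tuple[str, ...] = ("age", "sex"),
) -> InstrumentFit:
    """Regress the exposure on the PGS with covariate adjustment.

    ``r_squared`` is the incremental R-squared of the PGS term (full model
    minus covariates-only model), matching a report of "variance explained
    by the score" after adjustment.
    """
    df = cohort if PGS_COLUMN in cohort.columns else add_pgs(cohort)
    cols = [exposure, PGS_COLUMN, *covariates]
    sub = df[cols].dropna()
    sub = sub.assign(**{PGS_COLUMN: sub[PGS_COLUMN].astype(float)})
    k = len(covariates) + 2
    if len(sub) < max(10, k + 1):
        raise ValueError(f"too few complete rows ({len(sub)}) to fit the instrument")
    terms = " + ".join(_term(c, sub) for c in covariates) or "1"
    full = smf.ols(f"{exposure} ~ {PGS_COLUMN} + {terms}", data=sub).fit()
    reduced = smf.ols(f"{exposure} ~ {terms}", data=sub).fit()
    r2 = max(0.0, float(full.rsquared - reduced.rsquared))
    n = int(full.nobs)
    return InstrumentFit(
        beta_gx=float(full.params[PGS_COLUMN]),
        se_gx=float(full.bse[PGS_COLUMN]),
        p_gx=float(full.pvalues[PGS_COLUMN]),
        r_squared=r2,
        f_statistic=f_statistic(r2, n),
        n=n,
    )


def _term(col: str, df: pd.DataFrame) -> str:
    """Formula term: wrap non-numeric columns in C()."""
    return col if pd.api.types.is_numeric_dtype(df[col]) else f"C({col})"


def read_vcf_genotypes(path, effect_alleles: dict[str, str]) -> pd.DataFrame:
    """Extract effect-allele counts for named rsIDs from a VCF.

    ``effect_alleles`` maps rsID -> the 25(OH)D-lowering allele; counts are
    per-sample occurrences of that allele (0/1/2), whether it is REF or an
    ALT.  Returns one row per sample with columns ``g_<rsid>`` (nullable
    integers; missing genotypes stay missing).  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    found: dict[str, pd.array] = {}
    wanted = set(effect_alleles)
    for variant in vcf:
        rsid = variant.ID
        if rsid not in wanted:
            continue
        allele = effect_alleles[rsid]
        alleles = [variant.REF, *variant.ALT]
        if allele not in alleles:
            raise SchemaError(
                f"effect allele {allele!r} for {rsid} not among {alleles} in VCF"
            )
        target = alleles.index(allele)
        counts = []
        for g in variant.genotypes:  # [a1, a2, phased]
            pair = g[:2]
            if -1 in pair:
                counts.append(pd.NA)
            else:
                counts.append(sum(1 for a in pair if a == target))
        found[f"g_{rsid}"] = counts
    missing = wanted - {c[2:] for c in found}
    if missing:
        raise SchemaError(f"rsIDs not found in VCF: {sorted(missing)}")
    out = pd.DataFrame(found, index=samples).astype("Int64")
    out.index.name = "participant_id"
    return out


def check_pleiotropy(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Association of the PGS with putative outcome risk factors.

    Continuous covariates: OLS of the covariate on PGS (Wald p).
    Categorical covariates: multinomial logit of the covariate on PGS,
    likelihood-ratio p against the intercept-only model.  A uniformly
    non-significant set of p-values is evidence against horizontal
    pleiotropy through these measured pathways.
    """
    df = cohort if PGS_COLUMN in cohort.columns else add_pgs(cohort)
    rows = []
    for cov in covariates:
        sub = df[[cov, PGS_COLUMN]].dropna()
        pgs = sub[PGS_COLUMN].astype(float).to_numpy()
        if pd.api.types.is_numeric_dtype(sub[cov]):
            res = sm.OLS(sub[cov].astype(float).to_numpy(), sm.add_constant(pgs)).fit()
            p = float(res.pvalues[1])
            test = "linear"
        else:
            codes = pd.Categorical(sub[cov]).codes
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MNLogit(codes, sm.add_constant(pgs)).fit(disp=0)
            p = float(res.llr_pvalue)
            test = "multinomial"
        rows.append({"covariate": cov, "test": test, "p": p})
    out = pd.DataFrame(rows, columns=["covariate", "test", "p"])
    out.attrs["p_range"] = (
        (float(out["p"].min()), float(out["p"].max())) if len(out) else (np.nan, np.nan)
    )
    return out
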