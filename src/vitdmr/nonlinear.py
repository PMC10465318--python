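"""Non-linear Mendelian randomization via localized average causal effects.

The sample is split into K quantile strata of the instrument-free exposure
(residual 25(OH)D after regressing out the VD-PGS), so stratification does
not condition on a collider.  Within stratum j the localized average causal
effect (LACE) is the Wald ratio

    LACE_j = beta_ZY,j / beta_ZX,j,

approximating the derivative h'(x) of the causal effect function at the
stratum's mean exposure.  The LACEs are then meta-regressed against the
stratum mean 25(OH)D over the fractional-polynomial derivative family, and
three non-linearity tests are reported: the FP test (best degree-1 FP vs
the straight line, 1 df on the weighted-RSS difference), the quadratic
test (Wald test of the slope in a weighted regression of LACE on mean
exposure) and Cochran's Q for heterogeneity of the LACEs.  Two companion
diagnostics test constancy of the instrument-exposure association across
strata (Cochran's Q and a trend test on beta_ZX,j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import OneClassOutcomeError, SeparationError, WeakInstrumentError
from .fracpoly import DEGREE1_MODELS, DEGREE2_MODELS, FP_POWERS, fp_derivative_terms
from .genetics import PGS_COLUMN, add_pgs
from .mr import MR_COVARIATES, ratio_estimate
from .observational import OutcomeSpec, _design, _fit_logit_arrays, _prepare, build_outcomes


def instrument_free_exposure(
    cohort: pd.DataFrame,
    include_age_sex: bool = True,
    exposure: str = "vitd",
    covariates: tuple[str, ...] | None = None,
) -> pd.Series:
    """Residual exposure after regressing out the PGS (and, by default,
    age and sex, matching the MR adjustment set).

    Returned Series is aligned to the complete-case rows.  A constant PGS
    contributes nothing to the design, so the residual degenerates to the
    (covariate-adjusted) centred exposure.
    """
    df = cohort if PGS_COLUMN in cohort.columns else add_pgs(cohort)
    covs = covariates if covariates is not None else (("age", "sex") if include_age_sex else ())
    cols = [exposure, PGS_COLUMN, *covs]
    sub = df[cols].dropna()
    x = sub[exposure].to_numpy(dtype=float)
    Xc, _ = _design(sub.assign(outcome=0), covs)
    z = sub[PGS_COLUMN].to_numpy(dtype=float)
    X = Xc if np.ptp(z) == 0 else np.column_stack([Xc, z])
    resid = sm.OLS(x, X).fit().resid
    return pd.Series(resid, index=sub.index, name="iv_free_exposure")


def stratify_deciles(residuals: pd.Series, k: int = 10) -> pd.Series:
    """Rank-based assignment into K near-equal strata (1..K).

    Ties are broken by stable input order; stratum sizes differ by at most
    one (the first n mod K strata take the extra row).
    """
    n = len(residuals)
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} observations for {k} strata, got {n}")
    vals = np.asarray(residuals, dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("residuals are constant; quantiles are undefined")
    order = np.argsort(vals, kind="stable")
    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    labels = np.empty(n, dtype=int)
    start = 0
    for j, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = j
        start += size
    return pd.Series(labels, index=residuals.index, name="stratum")


@dataclass
class LaceStratum:
    """Per-stratum instrument associations and the localized causal effect."""

    index: int
    n_j: int
    n_cases: int
    x_mean: float
    beta_x_j: float = np.nan
    se_x_j: float = np.nan
    beta_y_j: float = np.nan
    se_y_j: float = np.nan
    lace_j: float = np.nan
    se_lace_j: float = np.nan
    usable: bool = True
    reason: str = ""


def strata_frame(strata: list[LaceStratum]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in strata])


def compute_laces(
    analysis_set: pd.DataFrame,
    assignment: pd.Series,
    covariates=MR_COVARIATES,
    use_stratum_beta_x: bool = True,
    beta_x_tol: float = 1e-8,
) -> list[LaceStratum]:
    """Stratum-wise Wald ratios (LACEs) with first-order Taylor SEs.

    Strata with a single outcome class, a degenerate within-stratum
    instrument slope, or separation in the logistic reduced form are
    flagged unusable (with a reason) rather than raising; downstream
    meta-regression drops them.  With ``use_stratum_beta_x=False`` the
    full-sample first-stage slope replaces the per-stratum one.
    """
    df = analysis_set.loc[assignment.index]
    full_beta_x = full_se_x = None
    if not use_stratum_beta_x:
        full_beta_x, full_se_x = _first_stage(df, covariates)
    out: list[LaceStratum] = []
    for j in sorted(assignment.unique()):
        sub = df.loc[assignment[assignment == j].index]
        y = sub["outcome"].to_numpy(dtype=float)
        stratum = LaceStratum(
            index=int(j), n_j=len(sub), n_cases=int(y.sum()),
            x_mean=float(sub["vitd"].mean()),
        )
        try:
            if use_stratum_beta_x:
                stratum.beta_x_j, stratum.se_x_j = _first_stage(sub, covariates)
            else:
                stratum.beta_x_j, stratum.se_x_j = full_beta_x, full_se_x
            if len(np.unique(y)) < 2:
                raise OneClassOutcomeError("single outcome class in stratum")
            Xc, _ = _design(sub, covariates)
            z = sub[PGS_COLUMN].to_numpy(dtype=float)
            logit = _fit_logit_arrays(y, np.column_stack([Xc, z]))
            stratum.beta_y_j = float(logit.params[-1])
            stratum.se_y_j = float(logit.bse[-1])
            stratum.lace_j, stratum.se_lace_j = ratio_estimate(
                stratum.beta_y_j, stratum.se_y_j, stratum.beta_x_j,
                stratum.se_x_j, tol=beta_x_tol,
            )
        except (OneClassOutcomeError, SeparationError, WeakInstrumentError,
                np.linalg.LinAlgError) as exc:
            stratum.usable = False
            stratum.reason = str(exc)
        out.append(stratum)
    return out


def _first_stage(sub: pd.DataFrame, covariates) -> tuple[float, float]:
    Xc, _ = _design(sub, covariates)
    z = sub[PGS_COLUMN].to_numpy(dtype=float)
    if np.ptp(z) == 0:
        raise WeakInstrumentError("PGS constant within stratum")
    res = sm.OLS(sub["vitd"].to_numpy(dtype=float), np.column_stack([Xc, z])).fit()
    return float(res.params[-1]), float(res.bse[-1])


def _wls(y: np.ndarray, B: np.ndarray, w: np.ndarray):
    """Weighted LS with known weights: (coef, cov, weighted RSS)."""
    sw = np.sqrt(w)
    Bw = B * sw[:, None]
    yw = y * sw
    coef, *_ = np.linalg.lstsq(Bw, yw, rcond=None)
    resid = yw - Bw @ coef
    wrss = float(resid @ resid)
    cov = np.linalg.pinv(Bw.T @ Bw)  # weights are inverse variances
    return coef, cov, wrss


def cochran_q(estimates: np.ndarray, ses: np.ndarray) -> tuple[float, float, float]:
    """(Q, p, pooled) — inverse-variance heterogeneity on K-1 df."""
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    est = np.asarray(estimates, dtype=float)
    pooled = float(np.sum(w * est) / np.sum(w))
    q = float(np.sum(w * (est - pooled) ** 2))
    p = float(stats.chi2.sf(q, len(est) - 1))
    return q, p, pooled


def instrument_constancy(strata: list[LaceStratum]) -> tuple[float, float]:
    """(p_Q, p_trend) for constancy of beta_ZX across strata.

    Cochran's Q over the per-stratum instrument-exposure slopes, and a
    Wald test of the slope in a weighted regression of beta_ZX,j on the
    stratum mean exposure.
    """
    usable = [s for s in strata if np.isfinite(s.beta_x_j) and np.isfinite(s.se_x_j)]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable strata, got {len(usable)}")
    bx = np.array([s.beta_x_j for s in usable])
    se = np.array([s.se_x_j for s in usable])
    xm = np.array([s.x_mean for s in usable])
    _, p_q, _ = cochran_q(bx, se)
    coef, cov, _ = _wls(bx, np.column_stack([np.ones_like(xm), xm]), 1.0 / se ** 2)
    z = coef[1] / np.sqrt(cov[1, 1])
    p_trend = float(2.0 * stats.norm.sf(abs(z)))
    return p_q, p_trend


@dataclass
class NonlinearMRResults:
    """Strata, non-linearity tests and instrument-constancy diagnostics."""

    spec: OutcomeSpec | None
    strata: list[LaceStratum]
    p_fp: float
    p_quadratic: float
    p_cochran_q: float
    best_fp1_power: float
    best_fp2_powers: tuple[float, float]
    pooled_lace: float
    se_pooled_lace: float
    p_q_instrument: float
    p_trend_instrument: float
    n: int
    n_excluded_strata: int
    skipped_models: list[tuple[tuple[float, ...], str]] = field(default_factory=list)

    def strata_frame(self) -> pd.DataFrame:
        return strata_frame(self.strata)

    def summary(self) -> str:
        label = self.spec.label if self.spec is not None else "LACE meta-regression"
        return (
            f"Non-linear MR ({label}): n = {self.n}, "
            f"{len(self.strata) - self.n_excluded_strata}/{len(self.strata)} usable strata\n"
            f"  pooled LACE = {self.pooled_lace:+.4f} log-odds per ng/mL "
            f"(SE {self.se_pooled_lace:.4f})\n"
            f"  P_fp = {self.p_fp:.4f}  P_quadratic = {self.p_quadratic:.4f}  "
            f"P_CochranQ = {self.p_cochran_q:.4f}\n"
            f"  best FP1 power = {self.best_fp1_power}  "
            f"best FP2 powers = {self.best_fp2_powers}\n"
            f"  instrument constancy: P_Q = {self.p_q_instrument:.4f}, "
            f"P_trend = {self.p_trend_instrument:.4f}"
        )


def _fp1_selection_pvalue(
    lace: np.ndarray, se: np.ndarray, xm: np.ndarray,
    n_boot: int = 4000, seed: int = 1848,
) -> tuple[float, float]:
    """Selection-aware FP test: best degree-1 FP vs the straight line.

    Every degree-1 candidate has a single free coefficient (the derivative
    basis is x^(p-1); the straight line is the p = 1 member), so the
    weighted-RSS improvement of the best candidate over linear is a pure
    model-selection maximum with no added parameters — a chi-square
    reference has no natural df for it.  The null distribution is instead
    obtained by parametric bootstrap: LACEs are redrawn about the pooled
    (constant-derivative) fit with their estimated SEs, and the selection
    statistic is recomputed.  Deterministic via the fixed internal seed.

    Returns (p_value, observed statistic).
    """
    w = 1.0 / se ** 2
    G = np.column_stack([fp_derivative_terms(xm, (p,)) for p in FP_POWERS])
    wG = w[:, None] * G
    denom = np.sum(wG * G, axis=0)  # sum w g^2 per candidate
    i_lin = FP_POWERS.index(1.0)

    def stat(y: np.ndarray) -> np.ndarray:
        # WRSS_0 - WRSS_g = (sum w g y)^2 / (sum w g^2) for one-coefficient fits
        gain = (y @ wG) ** 2 / denom
        return gain.max(axis=-1) - gain[..., i_lin]

    pooled = float(np.sum(w * lace) / np.sum(w))
    stat_obs = float(stat(lace))
    rng = np.random.Generator(np.random.PCG64(seed))
    sims = pooled + rng.standard_normal((n_boot, len(lace))) * se
    stat_null = stat(sims)
    p = (1.0 + np.sum(stat_null >= stat_obs - 1e-12)) / (n_boot + 1.0)
    return float(p), stat_obs


def fp_meta_regression(
    strata: list[LaceStratum],
    spec: OutcomeSpec | None = None,
    scale: float = 10.0,
    fp_test: str = "bootstrap",
) -> NonlinearMRResults:
    """Meta-regress LACEs on stratum mean exposure over the FP family.

    Each candidate effect function h(x) of degree 1 or 2 is fitted by
    regressing LACE_j on the derivative basis of h at the stratum means,
    weighted by 1/SE^2.  Three non-linearity tests are reported:

    - p_fp: best degree-1 FP vs the straight line (constant derivative).
      Default ``fp_test="bootstrap"`` uses the selection-aware parametric
      bootstrap of :func:`_fp1_selection_pvalue`; ``fp_test="chi2"`` refers
      the weighted-RSS difference to chi-square on 1 df (the
      function-selection convention, conservative here because the
      derivative bases are nearly collinear over the observed range).
    - p_quadratic: Wald test of the slope of LACE on mean exposure;
    - p_cochran_q: heterogeneity of the LACEs, chi-square on K-1 df.
    """
    usable = [s for s in strata if s.usable and np.isfinite(s.lace_j)]
    excluded = len(strata) - len(usable)
    if excluded:
        warnings.warn(f"{excluded} strata excluded from LACE meta-regression", stacklevel=2)
    if len(usable) < 4:
        raise ValueError(f"need >= 4 usable strata, got {len(usable)}")
    lace = np.array([s.lace_j for s in usable])
    se = np.array([s.se_lace_j for s in usable])
    xm = np.array([s.x_mean for s in usable]) / scale
    w = 1.0 / se ** 2

    skipped: list[tuple[tuple[float, ...], str]] = []

    def wrss_for(powers: tuple[float, ...]) -> float | None:
        B = fp_derivative_terms(xm, powers)
        if len(usable) <= B.shape[1]:
            skipped.append((powers, "fewer strata than parameters"))
            return None
        try:
            return _wls(lace, B, w)[2]
        except np.linalg.LinAlgError as exc:
            skipped.append((powers, str(exc)))
            return None

    d1 = {p: r for p in DEGREE1_MODELS if (r := wrss_for(p)) is not None}
    d2 = {p: r for p in DEGREE2_MODELS if (r := wrss_for(p)) is not None}
    best_d1 = min(d1, key=d1.get)
    best_d2 = min(d2, key=d2.get) if d2 else (np.nan, np.nan)
    wrss_linear = d1[(1.0,)]
    if fp_test == "bootstrap":
        p_fp, _ = _fp1_selection_pvalue(lace, se, xm)
    elif fp_test == "chi2":
        p_fp = float(stats.chi2.sf(max(0.0, wrss_linear - d1[best_d1]), 1))
    else:
        raise ValueError(f"fp_test must be 'bootstrap' or 'chi2', got {fp_test!r}")

    coef, cov, _ = _wls(lace, np.column_stack([np.ones_like(xm), xm]), w)
    zstat = coef[1] / np.sqrt(cov[1, 1])
    p_quadratic = float(2.0 * stats.norm.sf(abs(zstat)))

    q, p_q, pooled = cochran_q(lace, se)
    se_pooled = float(np.sqrt(1.0 / np.sum(w)))

    p_q_inst, p_trend_inst = instrument_constancy(strata)
    n = int(sum(s.n_j for s in strata))
    return NonlinearMRResults(
        spec=spec, strata=strata, p_fp=p_fp, p_quadratic=p_quadratic,
        p_cochran_q=p_q, best_fp1_power=float(best_d1[0]),
        best_fp2_powers=tuple(float(p) for p in best_d2),
        pooled_lace=pooled, se_pooled_lace=se_pooled,
        p_q_instrument=p_q_inst, p_trend_instrument=p_trend_inst,
        n=n, n_excluded_strata=excluded, skipped_models=skipped,
    )


class NonlinearMR:
    """Decile-stratified non-linear MR model for one outcome spec.

    Pipeline: complete-case analysis set -> instrument-free exposure
    residuals -> K rank-based strata -> per-stratum LACEs -> FP
    meta-regression and non-linearity tests.
    """

    def __init__(self, cohort: pd.DataFrame, outcome, covariates=MR_COVARIATES,
                 k: int = 10, include_age_sex_residual: bool = True,
                 use_stratum_beta_x: bool = True):
        if isinstance(outcome, str):
            trait, _, horizon = outcome.partition("_")
            outcome = OutcomeSpec(trait, horizon)
        self.spec = outcome
        self.covariates = tuple(covariates)
        self.k = k
        self.include_age_sex_residual = include_age_sex_residual
        self.use_stratum_beta_x = use_stratum_beta_x
        self.cohort = cohort if PGS_COLUMN in cohort.columns else add_pgs(cohort)

    def fit(self) -> NonlinearMRResults:
        analysis = build_outcomes(self.cohort, self.spec)
        sub = _prepare(analysis, self.covariates, ["vitd", PGS_COLUMN])
        sub.attrs = analysis.attrs
        resid = instrument_free_exposure(
            sub,
            covariates=self.covariates if self.include_age_sex_residual else (),
        )
        assignment = stratify_deciles(resid, self.k)
        strata = compute_laces(
            sub, assignment, covariates=self.covariates,
            use_stratum_beta_x=self.use_stratum_beta_x,
        )
        return fp_meta_regression(strata, spec=self.spec)
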