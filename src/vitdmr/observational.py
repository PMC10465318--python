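"""Traditional observational analysis.

Outcome construction over three annual waves, categorisation of serum
25(OH)D into deficiency (<20 ng/mL), insufficiency (20 to <30 ng/mL) and
sufficiency (>=30 ng/mL), covariate-adjusted logistic models for continuous
and categorical exposure, and fractional-polynomial tests of non-linearity
in the dose-response on the logit scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .exceptions import OneClassOutcomeError, SeparationError
from .fracpoly import DEGREE1_MODELS, DEGREE2_MODELS, fp_terms

TRAITS = ("si", "sp", "sa")
HORIZONS = ("baseline", "incident_1y", "incident_2y")

#: Full covariate set of the observational models.
OBSERVATIONAL_COVARIATES = (
    "sex", "age", "household_registration", "family_economy",
    "paternal_education", "maternal_education", "moderate_pa",
    "vigorous_pa", "impulsivity", "depression", "anxiety",
)

VITD_CATEGORIES = ("deficiency", "insufficiency", "sufficiency")


@dataclass(frozen=True)
class OutcomeSpec:
    """One analysis outcome: a trait (si/sp/sa) at a horizon.

    ``baseline`` uses the wave-1 report; ``incident_1y`` restricts to
    wave-1 negatives and uses the wave-2 report; ``incident_2y`` restricts
    to wave-1 negatives and scores positive if wave 2 and/or wave 3 is
    positive.  Restriction is per trait: only the trait's own baseline
    positives are excluded.
    """

    trait: str
    horizon: str

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}, got {self.trait!r}")
        if self.horizon not in HORIZONS:
            raise ValueError(f"horizon must be one of {HORIZONS}, got {self.horizon!r}")

    @property
    def label(self) -> str:
        return f"{self.trait}_{self.horizon}"


ALL_OUTCOME_SPECS = tuple(OutcomeSpec(t, h) for h in HORIZONS for t in TRAITS)


def build_outcomes(cohort: pd.DataFrame, spec: OutcomeSpec) -> pd.DataFrame:
    """Analysis set for one outcome spec, with an ``outcome`` column (0/1).

    Rows whose required waves are missing are dropped; the number dropped
    is recorded in ``result.attrs["n_dropped"]``.  Incident horizons keep
    only rows negative for the trait at wave 1.
    """
    w1, w2, w3 = (cohort[f"{spec.trait}_w{w}"] for w in (1, 2, 3))
    if spec.horizon == "baseline":
        keep = w1.notna()
        out = cohort.loc[keep].copy()
        out["outcome"] = w1.loc[keep].astype(int)
    elif spec.horizon == "incident_1y":
        keep = (w1 == 0) & w2.notna()
        out = cohort.loc[keep].copy()
        out["outcome"] = w2.loc[keep].astype(int)
    else:  # incident_2y: positive at wave 2 and/or wave 3
        pos = (w2 == 1) | (w3 == 1)
        neg = (w2 == 0) & (w3 == 0)
        keep = (w1 == 0) & (pos | neg)
        out = cohort.loc[keep].copy()
        out["outcome"] = pos.loc[keep].astype(int)
    out.attrs["n_dropped"] = int(len(cohort) - len(out))
    out.attrs["spec"] = spec
    return out


def categorize_vitd(vitd):
    """Clinical 25(OH)D category: <20 deficiency, 20 to <30 insufficiency,
    >=30 ng/mL sufficiency.  Accepts a scalar or a Series/array."""
    arr = np.asarray(vitd, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("vitd must be strictly positive")
    cats = np.select(
        [arr < 20.0, arr < 30.0], ["deficiency", "insufficiency"], "sufficiency"
    )
    cats = np.where(np.isnan(arr), None, cats)
    if np.isscalar(vitd) or np.ndim(vitd) == 0:
        return cats.item()
    if isinstance(vitd, pd.Series):
        return pd.Series(
            pd.Categorical(cats, categories=list(VITD_CATEGORIES)),
            index=vitd.index, name="vitd_cat",
        )
    return cats


@dataclass
class GlmFit:
    """Logistic-fit results: log-odds coefficients with Wald inference."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    llf: float
    n: int
    undefined: dict[str, str] = field(default_factory=dict)

    def _idx(self, term: str) -> int:
        matches = [i for i, t in enumerate(self.terms) if term in t]
        if not matches:
            raise KeyError(f"term {term!r} not in model ({self.terms})")
        return matches[0]

    def coef(self, term: str) -> float:
        return float(self.params[self._idx(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self._idx(term)])

    def p(self, term: str) -> float:
        return float(self.pvalues[self._idx(term)])

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        """(OR, lower, upper) with a 1.96-SE Wald interval."""
        b, s = self.coef(term), self.se(term)
        return float(np.exp(b)), float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s))

    def summary_frame(self) -> pd.DataFrame:
        lo = np.exp(self.params - 1.96 * self.bse)
        hi = np.exp(self.params + 1.96 * self.bse)
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "OR": np.exp(self.params),
             "ci_low": lo, "ci_high": hi, "p": self.pvalues},
            index=self.terms,
        )


def _fit_logit_arrays(y: np.ndarray, X: np.ndarray):
    """Binomial GLM fit with separation surfaced as SeparationError."""
    with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            if not res.converged:
                # IRLS can cycle on ill-conditioned FP designs; retry with lbfgs
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    method="lbfgs", maxiter=1000, disp=0)
            # force lazy attributes inside the suppression context
            res.llf, res.bse, res.pvalues
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation in logistic fit: {exc}") from exc
    if not getattr(res, "converged", True) or not np.isfinite(res.llf):
        raise SeparationError("logistic fit did not converge")
    return res


def _design(data: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design matrix via patsy (categoricals dummied).

    Covariates constant in this sample (e.g. sex within a sex stratum) are
    dropped rather than producing a singular design.
    """
    covariates = [c for c in covariates if data[c].nunique() > 1]
    terms = " + ".join(
        c if pd.api.types.is_numeric_dtype(data[c]) else f"C({c})" for c in covariates
    )
    formula = "1" if not terms else "1 + " + terms
    mat = patsy.dmatrix(formula, data, return_type="dataframe")
    return np.asarray(mat, dtype=float), list(mat.columns)


def _prepare(data: pd.DataFrame, covariates, extra_cols) -> pd.DataFrame:
    cols = list(dict.fromkeys(["outcome", *extra_cols, *covariates]))
    sub = data[cols].dropna()
    for c in cols:
        if pd.api.types.is_extension_array_dtype(sub[c]) and pd.api.types.is_numeric_dtype(sub[c]):
            sub[c] = sub[c].astype(float)  # nullable Int64 -> float for patsy/GLM
    return sub


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise OneClassOutcomeError("outcome has one class; cannot fit a logistic model")


def fit_continuous(
    analysis_set: pd.DataFrame,
    covariates=(),
    exposure: str = "vitd",
) -> GlmFit:
    """Adjusted logistic model of the outcome on continuous 25(OH)D.

    The exposure coefficient is the log-OR per 1 ng/mL.
    """
    sub = _prepare(analysis_set, covariates, [exposure])
    y = sub["outcome"].to_numpy(dtype=float)
    _check_two_classes(y)
    Xc, names = _design(sub, covariates)
    X = np.column_stack([Xc, sub[exposure].to_numpy(dtype=float)])
    res = _fit_logit_arrays(y, X)
    terms = names + [exposure]
    return GlmFit(terms, np.asarray(res.params), np.asarray(res.bse),
                  np.asarray(res.pvalues), float(res.llf), int(res.nobs))


def fit_categorical(
    analysis_set: pd.DataFrame,
    covariates=(),
    exposure: str = "vitd",
    reference: str = "deficiency",
) -> GlmFit:
    """Logistic model with 25(OH)D category dummies, deficiency as reference.

    An empty category yields no dummy; its contrast is reported in
    ``undefined`` while the remaining contrasts are still fitted.
    """
    sub = _prepare(analysis_set, covariates, [exposure])
    y = sub["outcome"].to_numpy(dtype=float)
    _check_two_classes(y)
    cat = categorize_vitd(sub[exposure])
    present = [c for c in VITD_CATEGORIES if (cat == c).any()]
    if len(present) < 2:
        raise OneClassOutcomeError("fewer than two 25(OH)D categories present")
    levels = [c for c in present if c != reference]
    Xc, names = _design(sub, covariates)
    dummies = np.column_stack([(cat == c).to_numpy(dtype=float) for c in levels])
    X = np.column_stack([Xc, dummies])
    res = _fit_logit_arrays(y, X)
    terms = names + [f"vitd_cat[{c}]" for c in levels]
    undefined = {c: "no participants in category"
                 for c in VITD_CATEGORIES if c not in present and c != reference}
    return GlmFit(terms, np.asarray(res.params), np.asarray(res.bse),
                  np.asarray(res.pvalues), float(res.llf), int(res.nobs),
                  undefined=undefined)


@dataclass
class FpTestResult:
    """Best fractional polynomials and the likelihood-ratio non-linearity tests.

    ``p_overall`` compares the best degree-2 FP against the covariates-only
    null on 4 df (two coefficients plus two selected powers).
    ``p_nonlinear`` compares it against the linear model on 2 df by
    default: the straight line is nested in every degree-2 candidate, so
    the deviance gain over linear reflects the two added coefficients;
    over clinically realistic 25(OH)D ranges the FP transforms are nearly
    collinear and power selection contributes no further deviance, which a
    larger df would overcharge (making the test conservative).  Pass
    ``df_nonlinear=3`` for the function-selection-procedure convention
    that budgets an extra df for power selection.
    """

    best_powers_d2: tuple[float, float]
    best_powers_d1: tuple[float]
    loglik_null: float
    loglik_linear: float
    loglik_best_d1: float
    loglik_best_d2: float
    p_overall: float
    p_nonlinear: float
    n: int
    skipped: list[tuple[tuple[float, ...], str]] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"FP search over degrees 1-2 (n = {self.n})\n"
            f"  best degree-1 powers: {self.best_powers_d1}  "
            f"best degree-2 powers: {self.best_powers_d2}\n"
            f"  P_overall (best d2 vs null)     = {self.p_overall:.4f}\n"
            f"  P_nonlinear (best d2 vs linear) = {self.p_nonlinear:.4f}"
        )


def fp_nonlinearity_test(
    analysis_set: pd.DataFrame,
    covariates=(),
    exposure: str = "vitd",
    scale: float = 10.0,
    df_nonlinear: int = 2,
) -> FpTestResult:
    """Search degree-1 and degree-2 fractional polynomials of the exposure.

    The exposure is divided by ``scale`` (and shifted if any value is
    non-positive) before the power transforms to keep x^3 numerically tame;
    this rescaling changes coefficients but no deviance or p-value.
    Candidates that fail to converge are skipped and recorded.
    """
    sub = _prepare(analysis_set, covariates, [exposure])
    y = sub["outcome"].to_numpy(dtype=float)
    _check_two_classes(y)
    x = sub[exposure].to_numpy(dtype=float) / scale
    if x.min() <= 0:
        x = x - x.min() + 0.1
    Xc, _ = _design(sub, covariates)
    n = len(y)

    def llf_for(powers: tuple[float, ...] | None) -> float:
        if powers is None:
            X = Xc
        else:
            T = fp_terms(x, powers)
            # standardize FP columns: affine, so the log-likelihood is
            # unchanged, but IRLS conditioning improves for extreme powers
            T = (T - T.mean(axis=0)) / np.where(T.std(axis=0) > 0, T.std(axis=0), 1.0)
            X = np.column_stack([Xc, T])
        return float(_fit_logit_arrays(y, X).llf)

    llf_null = llf_for(None)
    skipped: list[tuple[tuple[float, ...], str]] = []

    def best(models):
        results = {}
        for powers in models:
            try:
                results[powers] = llf_for(powers)
            except SeparationError as exc:
                skipped.append((powers, str(exc)))
                warnings.warn(f"FP candidate {powers} skipped: {exc}", stacklevel=2)
        if not results:
            raise SeparationError("no FP candidate converged")
        top = max(results, key=results.get)
        return top, results

    best_d1, d1_results = best(DEGREE1_MODELS)
    best_d2, d2_results = best(DEGREE2_MODELS)
    llf_linear = d1_results.get((1.0,), np.nan)
    llf_d1 = d1_results[best_d1]
    llf_d2 = d2_results[best_d2]
    p_overall = float(stats.chi2.sf(2.0 * (llf_d2 - llf_null), 4))
    p_nonlinear = float(stats.chi2.sf(max(0.0, 2.0 * (llf_d2 - llf_linear)), df_nonlinear))
    return FpTestResult(
        best_powers_d2=best_d2,
        best_powers_d1=best_d1,
        loglik_null=llf_null,
        loglik_linear=float(llf_linear),
        loglik_best_d1=float(llf_d1),
        loglik_best_d2=float(llf_d2),
        p_overall=p_overall,
        p_nonlinear=p_nonlinear,
        n=n,
        skipped=skipped,
    )
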