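"""Linear Mendelian randomization by the ratio-of-coefficients method.

With a single instrument Z (the VD-PGS), exposure X (serum 25(OH)D) and a
binary outcome Y, the IV estimate of the causal log-OR per ng/mL is

    beta_IV = beta_ZY / beta_ZX,

where beta_ZX comes from the age- and sex-adjusted linear first stage and
beta_ZY from the age- and sex-adjusted logistic reduced form.  The default
standard error is the first-order Taylor approximation
SE(beta_ZY)/|beta_ZX|; the second-order term (adding the first-stage
uncertainty) is available as an option.  Division is refused when the
instrument F-statistic falls below 10 unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import OneClassOutcomeError, WeakInstrumentError
from .genetics import PGS_COLUMN, InstrumentFit, add_pgs, f_statistic
from .observational import OutcomeSpec, _design, _fit_logit_arrays, _prepare, build_outcomes

MR_COVARIATES = ("age", "sex")


def ratio_estimate(
    beta_gy: float, se_gy: float, beta_gx: float, se_gx: float = 0.0,
    second_order: bool = False, tol: float = 1e-10,
) -> tuple[float, float]:
    """(beta_IV, SE) for the Wald ratio.

    First-order Taylor SE is se_gy/|beta_gx|; the second-order version adds
    the first-stage term beta_gy^2 se_gx^2 / beta_gx^4 under the square root.
    """
    if abs(beta_gx) < tol:
        raise WeakInstrumentError("instrument-exposure coefficient is degenerate (|beta_gx| ~ 0)")
    beta_iv = beta_gy / beta_gx
    var = se_gy ** 2 / beta_gx ** 2
    if second_order:
        var += beta_gy ** 2 * se_gx ** 2 / beta_gx ** 4
    return float(beta_iv), float(np.sqrt(var))


@dataclass
class RatioMRResults:
    """Results of a ratio-of-coefficients MR fit."""

    spec: OutcomeSpec
    instrument: InstrumentFit
    beta_gy: float
    se_gy: float
    beta_iv: float
    se_iv: float
    n: int
    n_cases: int
    second_order: bool = False

    @property
    def or_iv(self) -> float:
        return float(np.exp(self.beta_iv))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta_iv - 1.96 * self.se_iv)),
            float(np.exp(self.beta_iv + 1.96 * self.se_iv)),
        )

    @property
    def p_linear(self) -> float:
        if self.se_iv == 0:
            return 1.0 if self.beta_iv == 0 else 0.0
        return float(2.0 * stats.norm.sf(abs(self.beta_iv / self.se_iv)))

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"Ratio-of-coefficients MR: {self.spec.label} "
            f"(n = {self.n}, cases = {self.n_cases})\n"
            f"  first stage  beta_ZX = {self.instrument.beta_gx:+.4f} "
            f"(SE {self.instrument.se_gx:.4f}), F = {self.instrument.f_statistic:.2f}\n"
            f"  reduced form beta_ZY = {self.beta_gy:+.4f} (SE {self.se_gy:.4f})\n"
            f"  beta_IV = {self.beta_iv:+.4f} log-odds per ng/mL\n"
            f"  OR = {self.or_iv:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
            f"P_linear = {self.p_linear:.4f}"
        )


class RatioMR:
    """Individual-level linear MR model for one outcome spec.

    Parameters
    ----------
    cohort
        Cohort table (a ``pgs`` column is added from the genotype columns
        if absent).
    outcome
        An :class:`OutcomeSpec` or a "trait_horizon" string like
        "si_baseline".
    covariates
        Adjustment set for both stages; defaults to age and sex.
    min_f, allow_weak
        Refuse the ratio when the instrument F is below ``min_f`` unless
        ``allow_weak`` is set.
    """

    def __init__(self, cohort: pd.DataFrame, outcome, covariates=MR_COVARIATES,
                 min_f: float = 10.0, allow_weak: bool = False):
        if isinstance(outcome, str):
            trait, _, horizon = outcome.partition("_")
            outcome = OutcomeSpec(trait, horizon)
        self.spec = outcome
        self.covariates = tuple(covariates)
        self.min_f = min_f
        self.allow_weak = allow_weak
        self.cohort = cohort if PGS_COLUMN in cohort.columns else add_pgs(cohort)

    def fit(self, second_order: bool = False) -> RatioMRResults:
        analysis = build_outcomes(self.cohort, self.spec)
        sub = _prepare(analysis, self.covariates, ["vitd", PGS_COLUMN])
        y = sub["outcome"].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise OneClassOutcomeError(f"{self.spec.label}: outcome has one class")
        Xc, _ = _design(sub, self.covariates)
        z = sub[PGS_COLUMN].to_numpy(dtype=float)
        x = sub["vitd"].to_numpy(dtype=float)
        X_first = np.column_stack([Xc, z])

        first = sm.OLS(x, X_first).fit()
        reduced_ols = sm.OLS(x, Xc).fit()
        r2 = max(0.0, float(first.rsquared - reduced_ols.rsquared))
        n = len(y)
        instrument = InstrumentFit(
            beta_gx=float(first.params[-1]), se_gx=float(first.bse[-1]),
            p_gx=float(first.pvalues[-1]), r_squared=r2,
            f_statistic=f_statistic(r2, n), n=n,
        )
        if instrument.f_statistic < self.min_f and not self.allow_weak:
            raise WeakInstrumentError(
                f"instrument F = {instrument.f_statistic:.2f} < {self.min_f}; "
                "pass allow_weak=True to override"
            )
        logit = _fit_logit_arrays(y, X_first)
        beta_gy = float(logit.params[-1])
        se_gy = float(logit.bse[-1])
        beta_iv, se_iv = ratio_estimate(
            beta_gy, se_gy, instrument.beta_gx, instrument.se_gx,
            second_order=second_order,
        )
        return RatioMRResults(
            spec=self.spec, instrument=instrument, beta_gy=beta_gy, se_gy=se_gy,
            beta_iv=beta_iv, se_iv=se_iv, n=n, n_cases=int(y.sum()),
            second_order=second_order,
        )


@dataclass
class PowerResult:
    """Closed-form power of the IV test for a binary outcome."""

    n: int
    r_squared_gx: float
    case_fraction: float
    true_or: float  # per SD of the exposure
    alpha: float
    power: float
    ncp: float

    def summary(self) -> str:
        return (
            f"MR power (binary outcome): n = {self.n}, R^2_ZX = {self.r_squared_gx:.4f}, "
            f"case fraction = {self.case_fraction:.3f}, OR per SD = {self.true_or:.2f}, "
            f"alpha = {self.alpha}\n  NCP = {self.ncp:.3f}, power = {self.power:.3f}"
        )


def mr_power_binary(
    n: int, r_squared_gx: float, case_fraction: float, true_or: float,
    alpha: float = 0.05,
) -> PowerResult:
    """Normal-approximation power for an IV estimate on a binary outcome.

    Follows the closed form of the standard MR power calculator for binary
    outcomes: the true odds ratio per SD of the exposure is converted to a
    risk-scale slope b = K (OR / (1 + K (OR - 1)) - 1) at case fraction K,
    the IV estimator's variance is (K(1-K) - b^2) / (n R^2_ZX), and power
    is the tail mass of the non-central chi-square(1) beyond the alpha
    critical value.
    """
    if not (0.0 < r_squared_gx < 1.0):
        raise ValueError("r_squared_gx must lie in (0, 1)")
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case_fraction must lie in (0, 1)")
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    k = case_fraction
    b = k * (true_or / (1.0 + k * (true_or - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b * b) / (n * r_squared_gx)
    ncp = b * b / v
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    power = float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else alpha
    return PowerResult(n=int(n), r_squared_gx=r_squared_gx, case_fraction=k,
                       true_or=true_or, alpha=alpha, power=power, ncp=float(ncp))


@dataclass
class StratumUnavailable:
    """Placeholder for a sex stratum that could not be analysed."""

    stratum: str
    reason: str


def sex_stratified(cohort: pd.DataFrame, analysis, covariates=MR_COVARIATES, **kwargs):
    """Run an analysis separately in males and females.

    ``analysis`` is a callable ``(cohort_subset, covariates=...) -> result``;
    sex is dropped from the covariate set within each stratum.  Empty or
    failing strata yield :class:`StratumUnavailable` rather than raising.
    """
    within = tuple(c for c in covariates if c != "sex")
    out = {}
    for stratum in ("male", "female"):
        sub = cohort[cohort["sex"] == stratum]
        if len(sub) == 0:
            out[stratum] = StratumUnavailable(stratum, "no participants")
            continue
        try:
            out[stratum] = analysis(sub, covariates=within, **kwargs)
        except Exception as exc:  # surface, don't abort the other stratum
            out[stratum] = StratumUnavailable(stratum, str(exc))
    return out
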