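"""Synthetic cohort generator.

Emulates the statistical structure of a school-based adolescent cohort with
three annual waves of self-reported suicidality (ideation SI, plans SP,
attempts SA), serum 25-hydroxyvitamin D [25(OH)D] in ng/mL, and three
genotyped SNPs (rs10741657, rs4588, rs7041) whose 25(OH)D-lowering allele
counts form an unweighted polygenic score (VD-PGS).

The generative model is

    PGS_i   = sum of three Binomial(2, q_k) allele counts (HWE)
    X_i     = mu_x + beta_pgs * (PGS_i - E[PGS]) + gamma_x * C_i + eps_i
    logit P(Y_i = 1) = alpha + h(X_i) + gamma_y * C_i

where C_i ~ N(0,1) is a shared unobserved confounder, eps_i is Gaussian
noise scaled so the marginal SD of X matches the configured value, and the
causal effect function h is null, linear, or a below-threshold linear
segment.  Wave-1 intercepts are calibrated so marginal prevalences match
the configured baseline values; wave-2 and wave-3 outcomes are generated
conditionally on earlier waves so the configured 1-year and 2-year incident
rates hold among baseline-negative participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ConfigError

TRAITS = ("si", "sp", "sa")
SNPS = ("rs10741657", "rs4588", "rs7041")
GENOTYPE_COLUMNS = tuple(f"g_{s}" for s in SNPS)

#: Documented column order of the cohort CSV.
COHORT_COLUMNS = (
    "participant_id",
    "sex",
    "age",
    "household_registration",
    "family_economy",
    "paternal_education",
    "maternal_education",
    "moderate_pa",
    "vigorous_pa",
    "impulsivity",
    "depression",
    "anxiety",
    *GENOTYPE_COLUMNS,
    "vitd",
    "si_w1", "sp_w1", "sa_w1",
    "si_w2", "sp_w2", "sa_w2",
    "si_w3", "sp_w3", "sa_w3",
)

OUTCOME_COLUMNS = tuple(f"{t}_w{w}" for w in (1, 2, 3) for t in TRAITS)

# Named RNG substreams with fixed spawn keys: adding a new stream appends a
# new key and never perturbs columns drawn from earlier streams.
_STREAMS = (
    "demographics",
    "covariates",
    "genotypes",
    "confounder",
    "exposure_noise",
    "outcomes_w1",
    "outcomes_w2",
    "outcomes_w3",
    "missingness",
)


@dataclass(frozen=True)
class CausalModel:
    """Causal effect of 25(OH)D on the log-odds of each suicidality trait.

    kind
        "null": no effect; "linear": slope * (x - centre) everywhere;
        "threshold": slope * (x - threshold) below the threshold, zero above.
    slope
        log-odds per ng/mL 25(OH)D.
    threshold
        ng/mL; location of the change point for kind="threshold".
    """

    kind: str = "null"
    slope: float = 0.0
    threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("null", "linear", "threshold"):
            raise ConfigError(f"unknown causal model kind: {self.kind!r}")

    def effect(self, x: np.ndarray, centre: float) -> np.ndarray:
        """Evaluate h(x) (log-odds contribution), centred for identifiability."""
        x = np.asarray(x, dtype=float)
        if self.kind == "null":
            return np.zeros_like(x)
        if self.kind == "linear":
            return self.slope * (x - centre)
        # threshold: linear segment below the change point, flat above
        return self.slope * (np.minimum(x, self.threshold) - self.threshold)

    def derivative(self, x: np.ndarray) -> np.ndarray:
        """dh/dx at x — the estimand of a localized average causal effect."""
        x = np.asarray(x, dtype=float)
        if self.kind == "null":
            return np.zeros_like(x)
        if self.kind == "linear":
            return np.full_like(x, self.slope)
        return np.where(x < self.threshold, self.slope, 0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the marginal structure of the study population this
    generator emulates: n = 1,426 early adolescents, 60.8% male, age
    12.48 (SD 0.48) years, 25(OH)D 23.12 (SD 5.76) ng/mL, baseline SI/SP/SA
    prevalences 24.1%/10.1%/1.5%, 1-year incident rates 12.8%/7.8%/2.8% and
    2-year incident rates 25.6%/13.4%/4.1% among baseline-negatives, and a
    polygenic score explaining 3.97% of 25(OH)D variance.

    ``allele_freqs`` are frequencies of the 25(OH)D-LOWERING allele of
    rs10741657, rs4588 and rs7041 (placeholder values; the emulated study
    does not publish them), so ``pgs_beta`` is negative by convention.
    """

    n_participants: int = 1426
    male_fraction: float = 0.608
    age_mean_sd: tuple[float, float] = (12.48, 0.48)
    allele_freqs: tuple[float, float, float] = (0.6, 0.3, 0.25)
    pgs_beta: float | None = None  # None -> calibrated to target_r2
    target_r2: float = 0.0397
    exposure_mean_sd: tuple[float, float] = (23.12, 5.76)
    confounder_effect_exposure: float = 1.5  # ng/mL per confounder SD
    confounder_effect_outcome: float = 0.35  # log-odds per confounder SD
    causal_model: CausalModel = field(default_factory=CausalModel)
    baseline_prevalences: tuple[float, float, float] = (0.241, 0.101, 0.015)
    incident_rates_1y: tuple[float, float, float] = (0.128, 0.078, 0.028)
    incident_rates_2y: tuple[float, float, float] = (0.256, 0.134, 0.041)
    missing_rate: float = 0.0
    seed: int = 20260928

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_participants, (int, np.integer)) or self.n_participants < 20:
            raise ConfigError("n_participants must be an integer >= 20")
        props = {
            "male_fraction": self.male_fraction,
            "missing_rate": self.missing_rate,
            **{f"allele_freqs[{i}]": f for i, f in enumerate(self.allele_freqs)},
            **{f"baseline_prevalences[{i}]": p for i, p in enumerate(self.baseline_prevalences)},
            **{f"incident_rates_1y[{i}]": p for i, p in enumerate(self.incident_rates_1y)},
            **{f"incident_rates_2y[{i}]": p for i, p in enumerate(self.incident_rates_2y)},
        }
        for name, p in props.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} = {p} is not a proportion in [0, 1]")
        for i, f in enumerate(self.allele_freqs):
            if not (0.0 < f < 1.0):
                raise ConfigError(f"allele_freqs[{i}] must lie strictly in (0, 1)")
        for r1, r2, t in zip(self.incident_rates_1y, self.incident_rates_2y, TRAITS):
            if r2 < r1:
                raise ConfigError(
                    f"2-year incident rate for {t} ({r2}) below 1-year rate ({r1})"
                )
        if self.exposure_mean_sd[1] <= 0 or self.age_mean_sd[1] < 0:
            raise ConfigError("scale parameters must be positive")
        if self.pgs_beta is None and not (0.0 <= self.target_r2 < 1.0):
            raise ConfigError("target_r2 must lie in [0, 1)")

    def resolved_pgs_beta(self) -> float:
        """pgs_beta with the sign convention beta < 0 (lowering alleles)."""
        if self.pgs_beta is not None:
            return float(self.pgs_beta)
        return -calibrate_pgs_beta(self.target_r2, self)


def pgs_variance(allele_freqs) -> float:
    """Variance of a sum of independent HWE allele counts: sum 2 q (1-q)."""
    return float(sum(2.0 * q * (1.0 - q) for q in allele_freqs))


def calibrate_pgs_beta(target_r2: float, config: GeneratorConfig) -> float:
    """Per-allele effect magnitude giving the requested PGS R-squared.

    Solves Var(PGS) * beta^2 / sigma_x^2 = R^2 for |beta|, with sigma_x the
    configured marginal exposure SD.  Raises if the requested R-squared
    leaves no room for the residual noise once the confounder's exposure
    share is accounted for.
    """
    if not (0.0 <= target_r2 < 1.0):
        raise ConfigError("target_r2 must lie in [0, 1)")
    sigma = config.exposure_mean_sd[1]
    var_x = sigma ** 2
    beta = float(np.sqrt(target_r2 * var_x / pgs_variance(config.allele_freqs)))
    resid_var = var_x * (1.0 - target_r2) - config.confounder_effect_exposure ** 2
    if resid_var < 0:
        raise ConfigError(
            "target_r2 unattainable: PGS and confounder shares exceed the "
            "configured exposure variance"
        )
    return beta


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    return {
        name: np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(k,))))
        for k, name in enumerate(_STREAMS)
    }


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept a with mean(expit(a + eta)) = target on this sample."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    return brentq(lambda a: expit(a + eta).mean() - target, -40.0, 40.0)


def _draw_wave(
    eta: np.ndarray, target: float, rng: np.random.Generator, mask: np.ndarray
) -> np.ndarray:
    """Bernoulli outcomes for rows in ``mask`` with rate calibrated on them."""
    y = np.zeros(eta.shape[0], dtype=np.int64)
    if mask.sum() == 0:
        return y
    a = _solve_intercept(eta[mask], target)
    p = expit(a + eta[mask]) if np.isfinite(a) else (np.ones(mask.sum()) if a > 0 else np.zeros(mask.sum()))
    y[mask] = rng.binomial(1, p)
    return y


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one cohort table.

    Deterministic given ``config`` (including its seed): named RNG
    substreams with fixed spawn keys are used per column block.  Outcome
    columns are nullable integers (1 = yes, 0 = no, <NA> = missing).
    """
    config.validate()
    n = config.n_participants
    rng = _rngs(config.seed)

    sex = np.where(rng["demographics"].random(n) < config.male_fraction, "male", "female")
    age = rng["demographics"].normal(*config.age_mean_sd, size=n)

    cov = rng["covariates"]
    covariates = {
        "household_registration": cov.choice(["urban", "rural"], size=n, p=[0.55, 0.45]),
        "family_economy": cov.choice(["low", "middle", "high"], size=n, p=[0.2, 0.6, 0.2]),
        "paternal_education": cov.choice(["primary", "secondary", "tertiary"], size=n, p=[0.25, 0.5, 0.25]),
        "maternal_education": cov.choice(["primary", "secondary", "tertiary"], size=n, p=[0.3, 0.5, 0.2]),
        "moderate_pa": cov.integers(0, 8, size=n),
        "vigorous_pa": cov.integers(0, 8, size=n),
        "impulsivity": cov.normal(50.0, 10.0, size=n).round(2),
        "depression": cov.normal(10.0, 5.0, size=n).clip(0).round(2),
        "anxiety": cov.normal(8.0, 4.0, size=n).clip(0).round(2),
    }

    genotypes = {
        col: rng["genotypes"].binomial(2, q, size=n)
        for col, q in zip(GENOTYPE_COLUMNS, config.allele_freqs)
    }
    pgs = sum(genotypes.values())

    confounder = rng["confounder"].standard_normal(n)

    mu_x, sigma_x = config.exposure_mean_sd
    beta = config.resolved_pgs_beta()
    var_explained = beta ** 2 * pgs_variance(config.allele_freqs) + config.confounder_effect_exposure ** 2
    resid_var = sigma_x ** 2 - var_explained
    if resid_var < 0:
        raise ConfigError(
            "pgs_beta and confounder_effect_exposure imply more variance than "
            "the configured exposure SD allows"
        )
    e_pgs = 2.0 * float(np.sum(config.allele_freqs))
    vitd = (
        mu_x
        + beta * (pgs - e_pgs)
        + config.confounder_effect_exposure * confounder
        + rng["exposure_noise"].normal(0.0, np.sqrt(resid_var), size=n)
    )
    vitd = np.clip(vitd, 0.5, None)  # serum concentration is strictly positive

    eta_common = (
        config.causal_model.effect(vitd, centre=mu_x)
        + config.confounder_effect_outcome * confounder
    )

    outcomes: dict[str, np.ndarray] = {}
    all_rows = np.ones(n, dtype=bool)
    for k, trait in enumerate(TRAITS):
        y1 = _draw_wave(eta_common, config.baseline_prevalences[k], rng["outcomes_w1"], all_rows)
        neg1 = y1 == 0
        y2 = _draw_wave(eta_common, config.incident_rates_1y[k], rng["outcomes_w2"], neg1)
        # baseline-positives: persistence unconstrained downstream; keep at 1/2
        y2[~neg1] = rng["outcomes_w2"].binomial(1, 0.5, size=int((~neg1).sum()))
        r1, r2 = config.incident_rates_1y[k], config.incident_rates_2y[k]
        # P(w3 = yes | w1 = no, w2 = no) so that P(w2 or w3 | w1 = no) = r2
        cond = 0.0 if r1 >= 1.0 else (r2 - r1) / (1.0 - r1)
        neg12 = neg1 & (y2 == 0)
        y3 = _draw_wave(eta_common, cond, rng["outcomes_w3"], neg12)
        y3[~neg12] = rng["outcomes_w3"].binomial(1, 0.5, size=int((~neg12).sum()))
        outcomes[f"{trait}_w1"] = y1
        outcomes[f"{trait}_w2"] = y2
        outcomes[f"{trait}_w3"] = y3

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "sex": sex,
            "age": np.round(age, 2),
            **covariates,
            **genotypes,
            "vitd": np.round(vitd, 2),
            **{c: outcomes[c] for c in OUTCOME_COLUMNS},
        }
    )
    df = df[list(COHORT_COLUMNS)]
    for c in GENOTYPE_COLUMNS + OUTCOME_COLUMNS:
        df[c] = df[c].astype("Int64")

    if config.missing_rate > 0:
        miss_rng = rng["missingness"]
        for c in GENOTYPE_COLUMNS + ("vitd",) + OUTCOME_COLUMNS:
            mask = miss_rng.random(n) < config.missing_rate
            df.loc[mask, c] = pd.NA
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table as RFC-4180 CSV, outcomes as yes/no, missing empty."""
    out = df.copy()
    for c in OUTCOME_COLUMNS:
        if c in out.columns:
            out[c] = out[c].map({1: "yes", 0: "no"})
    out.to_csv(path, index=False, lineterminator="\r\n")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    for c in OUTCOME_COLUMNS:
        if c in df.columns:
            df[c] = df[c].map({"yes": 1, "no": 0, 1: 1, 0: 0}).astype("Int64")
    for c in GENOTYPE_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype("Int64")
    return df


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
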