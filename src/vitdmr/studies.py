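"""Replicate-based simulation studies over the synthetic cohort generator.

These drive the package end-to-end under known causal truths: estimator
recovery and interval coverage for the linear ratio method, type-I
calibration of the fractional-polynomial non-linearity tests, calibration
and power of the decile-stratified non-linear MR tests, and a Monte-Carlo
check of the closed-form binary-outcome power formula.  Every study takes
a single integer seed and derives per-replicate generator seeds from it.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .genetics import add_pgs
from .mr import RatioMR, mr_power_binary
from .nonlinear import NonlinearMR
from .observational import OutcomeSpec, build_outcomes, fp_nonlinearity_test
from .simulate import CausalModel, GeneratorConfig, generate_cohort

_SEED_MOD = 2**31 - 1


def replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate generator seeds below 2^31."""
    rng = np.random.Generator(np.random.PCG64(seed % _SEED_MOD))
    return rng.integers(0, _SEED_MOD, size=n)


def ratio_recovery_study(
    seed: int,
    n_participants: int = 10_000,
    slope: float = 0.05,
    n_replicates: int = 200,
    outcome: str = "si_baseline",
) -> dict:
    """Recovery of a linear causal slope by the ratio estimator.

    Returns the replicate mean of beta_IV, its Monte-Carlo SE, and the
    empirical 95%-CI coverage of the true slope.
    """
    betas, covered = [], 0
    for s in replicate_seeds(seed, n_replicates):
        cfg = GeneratorConfig(n_participants=n_participants, seed=int(s),
                              causal_model=CausalModel("linear", slope=slope))
        res = RatioMR(generate_cohort(cfg), outcome).fit()
        betas.append(res.beta_iv)
        lo = res.beta_iv - 1.96 * res.se_iv
        hi = res.beta_iv + 1.96 * res.se_iv
        covered += lo <= slope <= hi
    betas = np.asarray(betas)
    return {
        "true_slope": slope,
        "mean_beta_iv": float(betas.mean()),
        "mc_se": float(betas.std(ddof=1) / np.sqrt(len(betas))),
        "coverage": covered / len(betas),
        "n_replicates": len(betas),
        "n_participants": n_participants,
    }


def fp_type1_study(
    seed: int,
    n_participants: int = 3000,
    slope: float = 0.05,
    n_replicates: int = 500,
    alpha: float = 0.05,
    outcome: str = "si_baseline",
) -> dict:
    """Type-I error of the FP non-linearity test under a linear logit."""
    spec = OutcomeSpec(*outcome.split("_", 1))
    rej = 0
    pvals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in replicate_seeds(seed, n_replicates):
            cfg = GeneratorConfig(n_participants=n_participants, seed=int(s),
                                  causal_model=CausalModel("linear", slope=slope))
            analysis = build_outcomes(add_pgs(generate_cohort(cfg)), spec)
            fp = fp_nonlinearity_test(analysis, ["age", "sex"])
            pvals.append(fp.p_nonlinear)
            rej += fp.p_nonlinear < alpha
    return {
        "rejection_rate": rej / n_replicates,
        "alpha": alpha,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
        "p_values": pvals,
        "n_replicates": n_replicates,
        "n_participants": n_participants,
    }


def nonlinear_calibration_study(
    seed: int,
    n_participants: int = 2500,
    slope: float = 0.05,
    n_replicates: int = 500,
    alpha: float = 0.05,
    outcome: str = "si_baseline",
) -> dict:
    """Type-I error of the three non-linearity tests under a linear truth."""
    rej = {"p_fp": 0, "p_quadratic": 0, "p_cochran_q": 0, "p_q_instrument": 0}
    done = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in replicate_seeds(seed, n_replicates):
            cfg = GeneratorConfig(n_participants=n_participants, seed=int(s),
                                  causal_model=CausalModel("linear", slope=slope))
            nl = NonlinearMR(generate_cohort(cfg), outcome).fit()
            for key in rej:
                rej[key] += getattr(nl, key) < alpha
            done += 1
    return {
        "rejection_rates": {k: v / done for k, v in rej.items()},
        "alpha": alpha,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / done)),
        "n_replicates": done,
        "n_participants": n_participants,
    }


def threshold_power_study(
    seed: int,
    n_participants: int = 20_000,
    slope: float = -0.15,
    threshold: float = 20.0,
    n_replicates: int = 60,
    alpha: float = 0.05,
    outcome: str = "si_baseline",
) -> dict:
    """Power of the quadratic test against a below-threshold linear effect."""
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in replicate_seeds(seed, n_replicates):
            cfg = GeneratorConfig(
                n_participants=n_participants, seed=int(s),
                causal_model=CausalModel("threshold", slope=slope, threshold=threshold))
            nl = NonlinearMR(generate_cohort(cfg), outcome).fit()
            hits += nl.p_quadratic < alpha
    return {
        "power": hits / n_replicates,
        "n_replicates": n_replicates,
        "n_participants": n_participants,
        "slope": slope,
        "threshold": threshold,
    }


def power_formula_check(
    seed: int,
    n_participants: int = 1411,
    or_per_sd: float = 1.5,
    n_replicates: int = 200,
    alpha: float = 0.05,
    outcome: str = "si_baseline",
    confounded: bool = False,
) -> dict:
    """Monte-Carlo rejection rate of the ratio test vs the closed form.

    The generator slope is log(OR)/SD so the causal effect equals
    ``or_per_sd`` per exposure SD, the scale the closed form declares.
    By default the confounder paths are switched off so the simulation
    matches the closed form's assumption that the marginal and causal
    effects coincide; ``confounded=True`` keeps the generator defaults,
    under which logistic non-collapsibility attenuates the realized power
    below the closed form.
    """
    if confounded:
        base = GeneratorConfig()
    else:
        base = GeneratorConfig(confounder_effect_exposure=0.0,
                               confounder_effect_outcome=0.0)
    sd = base.exposure_mean_sd[1]
    slope = float(np.log(or_per_sd) / sd)
    hits = 0
    for s in replicate_seeds(seed, n_replicates):
        cfg = replace(base, n_participants=n_participants, seed=int(s),
                      causal_model=CausalModel("linear", slope=slope))
        res = RatioMR(generate_cohort(cfg), outcome, allow_weak=True).fit()
        hits += res.p_linear < alpha
    closed = mr_power_binary(n_participants, base.target_r2,
                             base.baseline_prevalences[0], or_per_sd, alpha)
    return {
        "monte_carlo_power": hits / n_replicates,
        "closed_form_power": closed.power,
        "n_replicates": n_replicates,
        "n_participants": n_participants,
        "or_per_sd": or_per_sd,
    }
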