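"""Config-driven orchestration of the full analysis.

``run_all`` executes, for every requested outcome (trait x horizon):
instrument construction and validation, the observational continuous and
categorical logistic models with the fractional-polynomial non-linearity
test, linear MR by the ratio of coefficients, and decile-stratified
non-linear MR — in the full sample and optionally per sex — and writes
TSV report tables plus a JSON run manifest.  Identical config and input
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError, SchemaError
from .genetics import add_pgs, check_pleiotropy, fit_instrument, screen_snps
from .mr import MR_COVARIATES, RatioMR, mr_power_binary
from .nonlinear import NonlinearMR
from .observational import (
    ALL_OUTCOME_SPECS,
    OBSERVATIONAL_COVARIATES,
    OutcomeSpec,
    build_outcomes,
    fit_categorical,
    fit_continuous,
    fp_nonlinearity_test,
)
from .simulate import (
    COHORT_COLUMNS,
    GENOTYPE_COLUMNS,
    OUTCOME_COLUMNS,
    read_cohort_csv,
)

logger = logging.getLogger("vitdmr")


@dataclass
class AnalysisConfig:
    """Settings for one end-to-end run."""

    input: str = ""
    outcomes: list[str] = field(default_factory=lambda: [s.label for s in ALL_OUTCOME_SPECS])
    covariates_observational: list[str] = field(
        default_factory=lambda: list(OBSERVATIONAL_COVARIATES))
    covariates_mr: list[str] = field(default_factory=lambda: list(MR_COVARIATES))
    category_cutoffs: tuple[float, float] = (20.0, 30.0)
    k_strata: int = 10
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "vitdmr_out"
    stratify_sex: bool = False
    power_calculation: bool = False
    power_or: float = 1.5

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.k_strata < 1:
            raise ConfigError("k_strata must be >= 1")
        for label in self.outcomes:
            trait, _, horizon = label.partition("_")
            OutcomeSpec(trait, horizon)  # raises on bad labels

    def specs(self) -> list[OutcomeSpec]:
        out = []
        for label in self.outcomes:
            trait, _, horizon = label.partition("_")
            out.append(OutcomeSpec(trait, horizon))
        return out

    def analysis_params(self) -> dict:
        """Config fields that determine the analysis (I/O locations excluded)."""
        d = asdict(self)
        d.pop("input", None)
        d.pop("out_dir", None)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.analysis_params(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationIssue:
    row: object
    column: str
    message: str


REQUIRED_COLUMNS = tuple(c for c in COHORT_COLUMNS)


def validate_schema(source) -> list[ValidationIssue]:
    """Check a cohort CSV (path) or DataFrame against the documented schema.

    Returns a machine-readable issue list; an empty list means the table
    is analysable.
    """
    if isinstance(source, (str, Path)):
        df = read_cohort_csv(source)
    else:
        df = source
    issues: list[ValidationIssue] = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            issues.append(ValidationIssue(None, col, "required column missing"))
    if issues:
        return issues
    for col in GENOTYPE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ~vals.isin([0, 1, 2])
        for row in df.index[bad]:
            issues.append(ValidationIssue(row, col, f"genotype {df.loc[row, col]!r} not in {{0,1,2}}"))
    vitd = pd.to_numeric(df["vitd"], errors="coerce")
    for row in df.index[df["vitd"].notna() & ~(vitd > 0)]:
        issues.append(ValidationIssue(row, "vitd", f"non-positive 25(OH)D value {df.loc[row, 'vitd']!r}"))
    for col in OUTCOME_COLUMNS:
        vals = df[col]
        bad = vals.notna() & ~vals.isin([0, 1])
        for row in df.index[bad]:
            issues.append(ValidationIssue(row, col, f"outcome {vals.loc[row]!r} not yes/no/missing"))
    bad_sex = df["sex"].notna() & ~df["sex"].isin(["male", "female"])
    for row in df.index[bad_sex]:
        issues.append(ValidationIssue(row, "sex", f"sex {df.loc[row, 'sex']!r} not male/female"))
    if not pd.api.types.is_numeric_dtype(pd.to_numeric(df["age"], errors="coerce")):
        issues.append(ValidationIssue(None, "age", "age is not numeric"))
    return issues


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return "NA" if not np.isfinite(x) else f"{x:.6g}"
    return str(x)


def _write_tsv(path: Path, columns: list[str], rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")


def _strata_for(config: AnalysisConfig, sex: str | None) -> list[tuple[str, object]]:
    groups: list[tuple[str, object]] = [("all", None)]
    if config.stratify_sex:
        groups += [("male", "male"), ("female", "female")]
    return groups


def run_all(config: AnalysisConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``).  Any
    stage failure is recorded per outcome (as NA rows plus a manifest
    entry) without aborting the remaining outcomes.
    """
    if cohort is None:
        cohort = read_cohort_csv(config.input)
    issues = validate_schema(cohort)
    if issues:
        first = issues[0]
        raise SchemaError(
            f"{len(issues)} schema issues; first: column {first.column!r}, "
            f"row {first.row!r}: {first.message}"
        )
    missing = [c for c in set(config.covariates_observational) | set(config.covariates_mr)
               if c not in cohort.columns]
    if missing:
        raise ConfigError(f"covariates not present in input table: {sorted(missing)}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run_all: %d outcomes, stratify_sex=%s", len(config.outcomes), config.stratify_sex)

    cohort = add_pgs(cohort)
    screen = screen_snps(cohort, alpha=config.alpha)
    instrument = fit_instrument(cohort)
    pleio_covs = [c for c in config.covariates_observational if c not in ("sex", "age")]
    pleiotropy = check_pleiotropy(cohort, pleio_covs)

    errors: dict[str, str] = {}
    t2_rows, t3_rows, t4_rows, diag_rows = [], [], [], []

    groups = _strata_for(config, None)
    for spec in config.specs():
        for group, sex in groups:
            sub = cohort if sex is None else cohort[cohort["sex"] == sex]
            obs_covs = [c for c in config.covariates_observational if sex is None or c != "sex"]
            mr_covs = [c for c in config.covariates_mr if sex is None or c != "sex"]
            key = f"{spec.label}/{group}"
            analysis = build_outcomes(sub, spec)
            row2 = {"outcome": spec.label, "group": group,
                    "n": len(analysis), "cases": int(analysis["outcome"].sum())}
            try:
                cont = fit_continuous(analysis, obs_covs)
                or_, lo, hi = cont.odds_ratio("vitd")
                fp = fp_nonlinearity_test(analysis, obs_covs)
                row2.update({"or_per_ngml": or_, "ci_low": lo, "ci_high": hi,
                             "p_linear": cont.p("vitd"), "p_overall": fp.p_overall,
                             "p_nonlinear": fp.p_nonlinear})
            except Exception as exc:
                errors[key + "/observational_continuous"] = str(exc)
            t2_rows.append(row2)

            try:
                catfit = fit_categorical(analysis, obs_covs)
                for cat in ("insufficiency", "sufficiency"):
                    term = f"vitd_cat[{cat}]"
                    row3 = {"outcome": spec.label, "group": group, "category": cat}
                    if cat in catfit.undefined:
                        row3["note"] = catfit.undefined[cat]
                    else:
                        or_, lo, hi = catfit.odds_ratio(term)
                        row3.update({"or_vs_deficiency": or_, "ci_low": lo,
                                     "ci_high": hi, "p": catfit.p(term), "note": ""})
                    t3_rows.append(row3)
            except Exception as exc:
                errors[key + "/observational_categorical"] = str(exc)

            row4 = {"outcome": spec.label, "group": group}
            try:
                lin = RatioMR(sub, spec, covariates=mr_covs).fit()
                lo, hi = lin.ci95
                row4.update({"n": lin.n, "or_iv": lin.or_iv, "ci_low": lo,
                             "ci_high": hi, "p_linear": lin.p_linear,
                             "f_statistic": lin.instrument.f_statistic})
            except Exception as exc:
                errors[key + "/mr_linear"] = str(exc)
            try:
                nl = NonlinearMR(sub, spec, covariates=mr_covs, k=config.k_strata).fit()
                row4.update({"p_fp": nl.p_fp, "p_quadratic": nl.p_quadratic,
                             "p_cochran_q": nl.p_cochran_q})
                for s in nl.strata:
                    diag_rows.append({
                        "outcome": spec.label, "group": group, "stratum": s.index,
                        "n_j": s.n_j, "cases": s.n_cases, "x_mean": s.x_mean,
                        "beta_x": s.beta_x_j, "se_x": s.se_x_j,
                        "beta_y": s.beta_y_j, "se_y": s.se_y_j,
                        "lace": s.lace_j, "se_lace": s.se_lace_j,
                        "usable": s.usable, "reason": s.reason,
                        "p_q_instrument": nl.p_q_instrument,
                        "p_trend_instrument": nl.p_trend_instrument,
                    })
            except Exception as exc:
                errors[key + "/mr_nonlinear"] = str(exc)
            t4_rows.append(row4)

    _write_tsv(out_dir / "table2_observational_continuous.tsv",
               ["outcome", "group", "n", "cases", "or_per_ngml", "ci_low", "ci_high",
                "p_linear", "p_overall", "p_nonlinear"], t2_rows)
    _write_tsv(out_dir / "table3_observational_categorical.tsv",
               ["outcome", "group", "category", "or_vs_deficiency", "ci_low",
                "ci_high", "p", "note"], t3_rows)
    _write_tsv(out_dir / "table4_mr.tsv",
               ["outcome", "group", "n", "or_iv", "ci_low", "ci_high", "p_linear",
                "f_statistic", "p_fp", "p_quadratic", "p_cochran_q"], t4_rows)
    _write_tsv(out_dir / "strata_diagnostics.tsv",
               ["outcome", "group", "stratum", "n_j", "cases", "x_mean", "beta_x",
                "se_x", "beta_y", "se_y", "lace", "se_lace", "usable", "reason",
                "p_q_instrument", "p_trend_instrument"], diag_rows)

    manifest = {
        "package_version": __version__,
        "config": config.analysis_params(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_input_rows": int(len(cohort)),
        "instrument": {
            "beta_gx": instrument.beta_gx, "se_gx": instrument.se_gx,
            "r_squared": instrument.r_squared,
            "f_statistic": instrument.f_statistic, "n": instrument.n,
        },
        "snp_screen": screen.to_dict(orient="records"),
        "pleiotropy_p_range": list(pleiotropy.attrs["p_range"]),
        "errors": errors,
        "library_versions": _library_versions(),
    }
    if config.power_calculation:
        spec0 = config.specs()[0]
        case_fraction = float(build_outcomes(cohort, spec0)["outcome"].mean())
        pw = mr_power_binary(instrument.n, max(instrument.r_squared, 1e-6),
                             case_fraction, config.power_or, config.alpha)
        manifest["power"] = {"outcome": spec0.label, "true_or_per_sd": config.power_or,
                             "power": pw.power}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _library_versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
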