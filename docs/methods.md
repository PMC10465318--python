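# Methods

## The analysis in brief

The package implements an individual-level Mendelian randomization (MR)
study of serum 25-hydroxyvitamin D [25(OH)D, ng/mL] on dichotomous
suicidality outcomes (ideation SI, plans SP, attempts SA) in an early
adolescent cohort followed over three annual waves, alongside the
traditional covariate-adjusted observational analysis.  The instrument is
an unweighted vitamin D polygenic score (VD-PGS): the per-participant
count of 25(OH)D-lowering alleles over rs10741657, rs4588 and rs7041.
Because the individual-level cohort data are not redistributable, a
synthetic cohort generator is a first-class, tested component: it
reproduces the marginal structure the analysis assumes and embeds
configurable causal truths (null, linear, threshold), so every stage can
be validated against a known answer.

## Outcomes

Baseline suicidality is the wave-1 report.  One-year incidence is a
wave-2 "yes" among participants negative for that trait at wave 1;
two-year incidence is a "yes" at wave 2 and/or wave 3 among wave-1
negatives.  Restriction is per trait: the SI incident set excludes only
baseline-SI positives.  For the two-year outcome, a row with wave-2 "no"
and wave-3 missing is indeterminate and is dropped; a wave-2 "yes" is a
case regardless of wave 3.  All models are complete-case within each
analysis set.

## The synthetic cohort generator

Defaults are the emulated study's conditions: n = 1,426; 60.8% male; age
12.48 (SD 0.48) years; 25(OH)D 23.12 (SD 5.76) ng/mL; baseline SI/SP/SA
prevalences 24.1%/10.1%/1.5%; 1-year incident rates 12.8%/7.8%/2.8% and
2-year rates 25.6%/13.4%/4.1% among baseline-negatives; PGS R² = 3.97%.
Genotypes are independent Binomial(2, q) draws (Hardy–Weinberg) with
placeholder lowering-allele frequencies 0.6/0.3/0.25 — the source study
does not publish them, and they matter only through Var(PGS).  The
per-allele effect is calibrated analytically:
|β| = SD·√(R²/Var(PGS)) ≈ 1.016 ng/mL per allele, negative by the
lowering-allele convention.

Exposure: X = μ + β(PGS − E[PGS]) + γₓC + ε, with C ~ N(0,1) a shared
latent confounder and ε scaled so the marginal SD equals the configured
value.  Defaults γₓ = 1.5 ng/mL and γ_y = 0.35 log-odds per confounder SD
give moderate, realistic confounding (observational bias without
overwhelming the outcome model).  Outcomes: each wave is Bernoulli with
logit = α + h(X) + γ_yC, where h is the configured causal effect (null;
linear slope·(x − μ); or slope·(x − t) below a threshold t and 0 above —
the deficiency-threshold shape).  Intercepts are calibrated per wave by
root-finding on the realized sample so marginal prevalences and
conditional incident rates match their targets; wave 3 among double
negatives targets (r₂ − r₁)/(1 − r₁).  Wave-2/3 status for
baseline-positives is unconstrained (it enters no analysis) and is drawn
at probability ½.

Randomness flows through named substreams with fixed spawn keys, so
adding a column block never perturbs earlier columns, and a fixed seed
gives byte-identical tables.  Missingness, when enabled, is completely at
random per cell.

What the generator does **not** emulate: linkage disequilibrium between
the three SNPs, genotyping error, population stratification, seasonality
of 25(OH)D, non-random missingness, and any joint covariate structure
beyond marginals (the demographic and psychiatric covariates are
generated independently and exist to exercise adjustment code paths).
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to those real-data features.

## Instrument metrics

The instrument fit regresses 25(OH)D on the PGS with age and sex; R² is
the *incremental* R² of the PGS term over the covariates-only model, and
F = (N−2)R²/(1−R²).  At the emulated study's values (R² = 0.0397,
N = 1,411) this returns F = 58.25.  The F > 10 convention gates the ratio
estimator (overridable).  Pleiotropy screening regresses each putative
risk factor on the PGS (linear for numeric covariates, multinomial
likelihood-ratio for categorical ones).

## Fractional polynomials and their degrees of freedom

FP searches use the standard power grid {−2, −1, −0.5, 0, 0.5, 1, 2, 3}
(0 ≡ log x; a repeated power p contributes x^p and x^p·log x).  The
exposure is divided by 10 first — an affine-in-design rescaling that
tames x³ and changes no deviance or p-value.  FP design columns are
standardized before IRLS for conditioning (again log-likelihood
invariant); candidates that still fail to converge are retried with
L-BFGS and otherwise skipped and recorded.

Two tests are reported from the observational FP search:

- **P_overall** — best degree-2 FP vs the covariates-only null, χ² on
  4 df (two coefficients + two selected powers).  Empirically calibrated
  under a no-association generator (rejection 0.047 at α = 0.05 over 300
  replicates of n = 3,000).
- **P_nonlinear** — best degree-2 FP vs the linear model, χ² on **2 df**
  by default.  The straight line is nested in every degree-2 candidate,
  so the deviance gain over linear is carried by the two added
  coefficients; over clinically realistic 25(OH)D ranges the FP
  transforms are nearly collinear and the power search contributes
  essentially no extra deviance.  This was verified directly: across
  1,000 linear-truth replicates the statistic's 50/90/95/99 percentiles
  (1.84/5.09/6.34/9.23) match χ²(2) (1.39/4.61/5.99/9.21); a 3-df
  reference — the function-selection convention that budgets a df for
  power selection — rejects at only 0.021 and is available via
  `df_nonlinear=3` for users who want that deliberate conservatism.

## Linear MR

β_IV = β_ZY/β_ZX with the age/sex-adjusted linear first stage and
logistic reduced form; SE defaults to the first-order Taylor form
SE(β_ZY)/|β_ZX| (the second-order term adding first-stage uncertainty is
available via `second_order=True`); Wald inference uses the normal
reference (n ≈ 1,400).  95% intervals use 1.96 throughout.

The reduced-form coefficient is a population-averaged (marginal) log-OR.
With a non-collapsible logit link and residual exposure/confounder
variation, the ratio estimator's estimand is therefore mildly attenuated
relative to the conditional slope of the generating model: at the default
confounding, a true slope of 0.05 log-odds per ng/mL is estimated at
0.0464 ± 0.0008 (600 replicates of n = 10,000), a 7% attenuation.  No
correction is applied — the method under study makes none — and the
recovery tests document this property rather than hide it.  95%-CI
coverage of the true slope is 0.94–0.95 in the same experiments.

Closed-form power for a binary outcome follows the standard MR power
calculator: the odds ratio per exposure SD is converted to a risk-scale
slope b = K(OR/(1 + K(OR − 1)) − 1) at case fraction K, the IV variance
is (K(1−K) − b²)/(N·R²_ZX), and power is the non-central χ²(1) tail at
the α critical value.  The formula assumes the marginal and causal
effects coincide; under the confounded default generator it overstates
realized power (0.307 vs 0.195 Monte-Carlo at OR 1.5/SD, n = 1,411), and
the package's oracle check therefore runs it against a confounder-free
generator (0.307 vs 0.247 at 400 replicates, within Monte-Carlo error
plus a documented risk-scale allowance).

## Non-linear MR

The instrument-free exposure is the residual of 25(OH)D on the PGS (age
and sex included by default to match the MR adjustment set; a PGS-only
residualization is available).  Ranks split the sample into K = 10
near-equal strata (sizes differ by at most one; ties broken by stable
input order).  Within each stratum the LACE is the Wald ratio of the
stratum-specific instrument-outcome and instrument-exposure associations
with the first-order SE; the stratum-specific first stage is the default
because the instrument-constancy diagnostics examine exactly those
per-stratum slopes (a full-sample first stage is available).  Strata with
a single outcome class, separation, or a degenerate first stage are
flagged and excluded from the meta-regression with K reduced and a
warning.

Meta-regression fits the *derivative* parameterization: a LACE
approximates h′(x) at the stratum mean, and d/dx of the FP family maps
power p to the plain-power basis x^(p−1) (with x^(p−1)·log x for repeated
powers).  Candidates are fitted by weighted least squares with inverse
LACE-variance weights treated as known.  Three tests are reported:

- **P_quadratic** — Wald test of the slope in the weighted regression of
  LACE on stratum mean exposure.
- **P_CochranQ** — inverse-variance heterogeneity of the LACEs, χ² on
  K−1 df.
- **P_fp** — best degree-1 FP vs the straight line.  Both models have
  exactly one free coefficient, so the weighted-RSS gain of the selected
  candidate is a pure model-selection maximum with no natural χ² df.  The
  default reference distribution is a parametric bootstrap (4,000 draws
  of the LACEs about the pooled constant-derivative fit with their
  estimated SEs, fixed internal seed — deterministic); the 1-df χ²
  convention of the originating methodology is available via
  `fp_test="chi2"` and is conservative here for the same collinearity
  reason as above (measured type-I 0.018 vs 0.048 for the bootstrap, at
  nominal 0.05 over 500 replicates).

Instrument constancy across strata is tested by Cochran's Q on the
per-stratum first-stage slopes and by a weighted trend test of those
slopes on stratum mean exposure.

Measured operating characteristics under the default conditions
(replicates of n = 2,500 linear-truth cohorts; 500 replicates): type-I
error at α = 0.05 is 0.048 (FP bootstrap), 0.060 (quadratic), 0.048
(Cochran's Q), 0.038 (instrument-constancy Q).  Against a strong
deficiency-threshold effect (slope −0.15 log-odds per ng/mL below
20 ng/mL, zero above) at n = 20,000, the quadratic test's power is ~0.93
(60 replicates).

## Pipeline conventions

`run_all` executes instrument construction, both observational models,
the FP search, linear MR and non-linear MR for every requested
trait × horizon, in the full sample and optionally per sex (sex leaves
the covariate set inside strata; covariates constant within a stratum are
dropped from designs).  Failures are recorded per outcome without
aborting the rest.  The manifest carries the analysis parameters and a
hash of them, the seed, and library versions — but no timestamp or I/O
paths, so identical config and input reproduce the bundle byte for byte.
Observational models adjust for sex, age, household registration, family
economy, parental education, physical activity and the psychiatric scores
(impulsivity, depression, anxiety); MR models adjust for age and sex
only.  No multiple-testing correction is applied anywhere.

## Problem sizes used in the validation studies

The replicate studies run at: ratio recovery, 200 × n = 10,000;
FP type-I, 500 × n = 3,000; non-linear MR calibration, 500 × n = 2,500;
threshold power, 60 × n = 20,000; power-formula check, 200–400 ×
n = 1,411.  These sizes give Monte-Carlo bands (3 binomial SEs for
rejection rates) tight enough to detect meaningful miscalibration while
keeping each study in the minutes range on a single CPU.

## Known limitations

- Single-instrument design: no MR-Egger, weighted-median or other
  multi-instrument sensitivity analyses; per-SNP Wald ratios are exposed
  only as diagnostics.
- The logistic reduced form's non-collapsibility attenuation (above) is
  inherited, not corrected.
- Decile stratification follows the residual-based construction; the
  doubly-ranked variant is not implemented.
- The generator's covariates are independent of genotype and exposure by
  construction, so adjustment changes little in simulation; on real data
  the covariate set matters.
- Sparse outcomes (SA at 1.5% baseline prevalence) routinely produce
  strata without cases in small samples; such strata are excluded with a
  warning rather than merged.
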