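# vitdmr

Linear and non-linear Mendelian randomization (MR) of serum
25-hydroxyvitamin D [25(OH)D] on adolescent suicidality — suicidal
ideation (SI), plans (SP) and attempts (SA) over three annual waves —
together with the traditional observational analysis it is compared
against, and a synthetic cohort generator that reproduces the statistical
structure of the school-based cohort the analysis was designed for.

It is written for epidemiologists and biostatisticians who want a tested,
reusable implementation of this analysis pattern:

- **Instrument construction** — an unweighted vitamin D polygenic score
  (VD-PGS): the count of 25(OH)D-lowering alleles of rs10741657 (*CYP2R1*),
  rs4588 and rs7041 (*GC*); per-SNP screening against the exposure;
  strength via the incremental R² and *F* = (N−2)R²/(1−R²); pleiotropy
  checks of the score against measured risk factors.
- **Observational models** — covariate-adjusted logistic regression on
  continuous 25(OH)D and on the clinical categories (deficiency < 20,
  insufficiency 20–<30, sufficiency ≥ 30 ng/mL), plus Royston–Altman
  fractional-polynomial (FP) searches over powers {−2, −1, −0.5, 0, 0.5,
  1, 2, 3} with likelihood-ratio tests for non-linearity.
- **Linear MR** — the ratio-of-coefficients (Wald) estimator
  β_IV = β_ZY / β_ZX from an age/sex-adjusted linear first stage and
  logistic reduced form, first-order Taylor SE = SE(β_ZY)/|β_ZX|, a weak
  instrument guard at F < 10, and a closed-form binary-outcome power
  calculator.
- **Non-linear MR** — decile stratification on the instrument-free
  exposure (residual 25(OH)D after regressing out the PGS), per-stratum
  localized average causal effects (LACEs), inverse-variance
  meta-regression of LACEs over the FP derivative family, and three
  non-linearity tests (FP, quadratic, Cochran's Q) plus
  instrument-constancy diagnostics.

## Worked example

```python
from vitdmr import GeneratorConfig, CausalModel, generate_cohort, \
    fit_instrument, add_pgs, RatioMR, NonlinearMR

cfg = GeneratorConfig(n_participants=10_000, seed=3,
                      causal_model=CausalModel("linear", slope=0.05))
cohort = add_pgs(generate_cohort(cfg))

print(fit_instrument(cohort).summary())
print(RatioMR(cohort, "si_baseline").fit().summary())
print(NonlinearMR(cohort, "si_baseline").fit().summary())
```

prints

```
Instrument (VD-PGS -> 25(OH)D, adjusted for age and sex)
  beta = -0.9963 ng/mL per allele (SE 0.0494, p = 8.17e-89)
  incremental R^2 = 0.0392   F = 407.39   N = 10000
Ratio-of-coefficients MR: si_baseline (n = 10000, cases = 2377)
  first stage  beta_ZX = -0.9963 (SE 0.0494), F = 407.39
  reduced form beta_ZY = -0.0414 (SE 0.0207)
  beta_IV = +0.0415 log-odds per ng/mL
  OR = 1.042 (95% CI 1.001-1.086), P_linear = 0.0453
Non-linear MR (si_baseline): n = 10000, 10/10 usable strata
  pooled LACE = +0.0422 log-odds per ng/mL (SE 0.0211)
  P_fp = 0.7863  P_quadratic = 0.7743  P_CochranQ = 0.1953
  best FP1 power = 2.0  best FP2 powers = (-2.0, -2.0)
  instrument constancy: P_Q = 0.8108, P_trend = 0.2541
```

Reading it: the score lowers 25(OH)D by ~1 ng/mL per allele and is a
strong instrument (F ≫ 10).  The cohort was generated with a true linear
causal slope of 0.05 log-odds per ng/mL; the ratio estimator returns
β_IV = 0.0415 (OR 1.042 per ng/mL), and all three non-linearity tests are
non-significant, as they should be under a linear truth.

The same pipeline runs from the shell:

```bash
vitdmr simulate --out cohort.csv --seed 1
vitdmr validate cohort.csv
vitdmr run --input cohort.csv --out reports/ --stratify-sex
```

`run` writes `table2_observational_continuous.tsv`,
`table3_observational_categorical.tsv`, `table4_mr.tsv`,
`strata_diagnostics.tsv` and a `manifest.json`; identical config and input
give byte-identical outputs.

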