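# mimosa

**M**issing-data **I**mputation, **MO**delling and **S**ensitivity **A**nalysis
for observational studies.

Missing data are everywhere in observational research, and the two standard
responses — restricting to complete records, or multiply imputing and hoping
— both rest on untestable assumptions about *why* values are missing.
`mimosa` packages the full workflow a careful analyst follows into tested,
reproducible code:

1. **Simulate** cohorts with a known exposure effect and explicit MCAR / MAR
   / MNAR missingness mechanisms (per-variable logistic deletion models with
   an optional self-dependence knob), retaining the pre-deletion truth so
   every downstream claim can be checked against it.
2. **Diagnose**: per-variable missingness and patterns, complete-vs-
   incomplete comparison, and a logistic model for the predictors of being a
   complete record.
3. **Plan**: a deterministic, fully auditable rule engine mapping the
   diagnostics to a strategy (complete-records vs multiple imputation, with
   or without sensitivity analysis), with every verdict citing its evidence.
4. **Impute**: a from-scratch fully-conditional-specification (chained
   equations) engine with proper Bayesian linear, Bayesian logistic,
   predictive-mean-matching and polytomous column models.
5. **Pool**: Rubin's rules — Q̄, Ū, B, T = Ū + (1+1/m)B, Barnard–Rubin
   degrees of freedom, fraction of missing information — plus the
   complete-records analysis for comparison.
6. **Stress-test**: pattern-mixture sensitivity analysis — a δ offset on the
   imputation model's linear predictor (log-odds units for a binary
   exposure), the worst-case deterministic fill, and a tipping-point search
   for the smallest δ that overturns the conclusion.
7. **Report**: a results table (method / n / coefficient / 95% CI / p / %
   imputed positive), the diagnostics, the strategy rationale, and an
   automatic agreement note — as markdown and round-trippable JSON.

The intended audience is biostatisticians and epidemiologists who want the
missing-data part of an analysis to be explicit, reproducible and
stress-tested rather than an afterthought.

## The model

The substantive model is a linear regression of a continuous outcome score
on a binary exposure adjusted for confounders; the estimand is the exposure
coefficient β (adjusted mean difference, outcome points).  Each of m
completed data sets yields (Q̂_i, U_i); Rubin's rules combine them:

```
Q̄ = mean(Q̂_i)    Ū = mean(U_i)    B = var(Q̂_i)
T = Ū + (1 + 1/m)·B        riv = (1 + 1/m)·B/Ū
fmi = (riv + 2/(ν+3)) / (1 + riv)
```

with ν the Barnard–Rubin degrees of freedom and CIs from the t reference.
The pattern-mixture sensitivity model assumes the conditional log-odds of
the exposure differ by δ between unobserved and observed records; δ = 0 is
the primary (MAR) analysis, and the default grid {0, 0.1, 0.25, 0.5, 1, 10}
runs to an extreme MNAR mechanism.  See `docs/methods.md` for the full
account.

## Worked example

```bash
mimosa pipeline --n 2000 --seed 42 --m 25 --cycles 10 --out-dir run
```

simulates a cohort of 2 000 (true effect −10 outcome points; ~51% of the
exposure and, overall, ~77% of records incomplete), runs diagnostics, the
strategy engine, 25 chained-equations imputations, pooling, the complete-
records analysis and the δ grid, and prints the results table:

```
| Method of analysis | n | Coefficient | 95% CI | P | % imputed positive |
| --- | --- | --- | --- | --- | --- |
| Primary analysis: multiple imputation | 2000 | -10.4 | (-11.9, -9.0) | <0.001 | 24.2 |
| Complete records analysis | 480 | -8.3 | (-11.1, -5.5) | <0.001 | N/A |
| Sensitivity analysis - delta = 0 | 2000 | -10.4 | (-11.9, -9.0) | <0.001 | 24.2 |
| Sensitivity analysis - delta = 0.1 | 2000 | -10.5 | (-11.9, -9.1) | <0.001 | 24.8 |
| Sensitivity analysis - delta = 0.25 | 2000 | -10.5 | (-11.9, -9.1) | <0.001 | 25.7 |
| Sensitivity analysis - delta = 0.5 | 2000 | -10.5 | (-11.9, -9.1) | <0.001 | 27.3 |
| Sensitivity analysis - delta = 1 | 2000 | -10.5 | (-11.9, -9.0) | <0.001 | 30.7 |
| Sensitivity analysis - delta = 10 | 2000 | -7.5 | (-8.5, -6.4) | <0.001 | 99.5 |
```

Reading it: the multiple-imputation estimate (−10.4 points, full n,
bracketing the true −10) is the primary result; the complete-records
estimate (−8.3 on less than a quarter of the sample) is attenuated, as
expected when missingness tracks the outcome; the δ rows show the conclusion
is
stable under increasingly severe assumptions that non-responders smoke
more than their observed data suggest — only the extreme δ = 10 row (which
imputes essentially every missing value as "smoker", last column ≈ 100%)
attenuates the estimate, by mixing mislabelled nonsmokers into the exposed
group, and even it stays far from the null.  The same numbers land in
`run/report.md`, `run/report.json` and the per-imputation stack under
`run/stack/`.

The library surface mirrors the CLI — `alspac_like_preset`,
`summarize_missingness`, `recommend_strategy`, `run_chained`, `pool_rubin`,
`run_delta_grid`, `find_tipping_point`, `build_report`, … — see the module
docstrings.

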