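# Methods

`mimosa` implements a complete treatment-and-reporting workflow for missing
data in observational exposure–outcome studies: diagnose the missingness,
choose a strategy through an explicit rule engine, run chained-equations
multiple imputation (MI), pool with Rubin's rules, and probe the untestable
missing-not-at-random (MNAR) assumption with pattern-mixture δ offsets.  This
note records the models, the defaults and why they are what they are, what
the synthetic cohorts do and do not emulate, and the numerical choices.

## The substantive model and estimand

The analysis model throughout is a linear regression of a continuous,
bounded outcome score (0–100) on a binary exposure adjusted for confounders;
the estimand is the exposure coefficient — the adjusted mean difference in
outcome-score points between exposed and unexposed.  Fits are ordinary least
squares (via statsmodels); categorical confounders enter as treatment-coded
dummies.  Coefficients are always reported in raw outcome units, never
standardized.

## Missingness taxonomy and the mechanism model

Each incomplete variable carries a logistic missingness model:

    P(cell missing) = expit(α + Σ_v β_v · value_v + δ_true · own value)

MCAR is the special case with all coefficients zero; MAR allows dependence on
stored variables but requires `δ_true = 0`; any non-zero self-coefficient
`δ_true` makes the mechanism MNAR by construction.  Deletion events are
independent Bernoulli draws per cell given the row.  A `monotone_dropout`
flag optionally nests missingness across declared wave order.

## The chained-equations engine

Fully conditional specification: each of `cycles` sweeps visits the
incomplete variables in a fixed order — ascending missingness count (most
missing last), ties by declaration order, which stabilizes early cycles and
is reproducible — regressing each on the *current* completed values of its
declared predictors and redrawing its missing cells.  All imputation is
proper (parameters drawn from their posterior before values):

* **Bayesian linear** — residual variance from its scaled inverse-χ²
  posterior, coefficients from the conditional normal, then linear
  predictor + δ + Gaussian noise.
* **Bayesian logistic** — Newton–Raphson MLE with a 1e-6 ridge for
  invertibility; the coefficient vector is drawn from the asymptotic normal
  approximation at the MLE (exact Bayes is out of scope; this matches
  mainstream chained-equations software).  Runaway coefficients (|β| > 12)
  signal separation and trigger a strongly penalized refit (ridge 1.0) with
  a recorded warning.
* **Predictive mean matching** — type-1 matching: observed rows scored with
  the least-squares coefficients, missing rows with a posterior draw; one of
  the `k = 5` nearest donors is copied, ties broken at the lowest row index.
  The distance matrix is computed in blocks to bound memory.
* **Polytomous** (categorical, >2 levels) — one-vs-rest logistic draws
  normalized to a single categorical draw; keeps the engine to two
  regression primitives, at the cost of not being a true multinomial model
  (a documented limitation).

Defaults `m = 25` imputations and `cycles = 10` follow common chained-
equations practice; both are configuration-exposed.  Starting values fill
each missing cell with a uniform draw from that variable's observed values.
Observed cells are never modified — the engine passes them through
bit-exactly.  One named RNG substream per (operation, variable, imputation)
— derived by hashing the name chain into a `SeedSequence` — guarantees that
adding a variable never perturbs earlier draws and that every run is a pure
function of its seed.

### δ offsets (pattern-mixture sensitivity)

For a flagged variable the offset δ is added to the linear predictor
(binary targets; log-odds units) or to the imputed values (continuous
targets; outcome units) **at every cycle**, only while imputing that
variable.  Positive δ on a binary exposure raises the log-odds of the "1"
level among imputed values.  For predictive-mean-matching targets δ shifts
the missing rows' predicted means before matching, so imputed values remain
donor-pool members.  Binary draws compare a uniform variate to the drawn
probability, and every column model consumes the same number of variates
regardless of δ, so δ runs sharing a seed are coupled by common random
numbers: the δ = 0 run reproduces the primary analysis bit-for-bit, and
differences along the grid are attributable to δ rather than Monte-Carlo
noise.  The default grid {0, 0.1, 0.25, 0.5, 1, 10} spans negligible to
extreme departures from MAR, with 0 as the equivalence anchor.  Offsets are
applied to a single variable in the standard workflow; multi-variable
offsets are accepted by the configuration but are untested territory.

### Worst-case imputation

The crude bounding analysis deterministically fills every missing cell of
the flagged variable with a chosen level (e.g. "everyone with missing
smoking status smoked") in all m copies; remaining variables are imputed
normally.  Because a binary mechanism cannot make *everyone* exposed, the
worst-case contrast mixes truly exposed records with mislabelled unexposed
ones and attenuates a genuine effect toward the null.

## Rubin's rules and inference

With per-imputation estimates Q̂_i and squared standard errors U_i:

    Q̄ = mean Q̂_i        Ū = mean U_i        B = var(Q̂_i)
    T = Ū + (1 + 1/m)·B   riv = (1 + 1/m)·B/Ū

Degrees of freedom use the Barnard–Rubin small-sample adjustment

    ν = [1/ν_classic + 1/ν_obs]⁻¹,   ν_classic = (m−1)(1 + 1/riv)²,
    ν_obs = ((ν_com+1)/(ν_com+3))·ν_com·(1−λ),   λ = (1+1/m)B/T

with ν_com the complete-data residual df; the classic large-sample form is
available via `df_method="classic"` for cross-checking other software.  The
fraction of missing information is fmi = (riv + 2/(ν+3))/(1+riv).  CIs and
two-sided p-values use the t reference with the pooled df (the reference
distribution is a package choice).  When B = 0 the pooled df falls back to
the complete-data df.  All intermediate quantities (Q̂_i, U_i, B, Ū, df) are
serialized for auditability.

## The strategy flowchart

Three questions, answered from the diagnostics plus substantive-knowledge
flags that are deliberately *inputs*, never inferred:

* **Q1** (complete-records validity): requires the incomplete-record
  proportion strictly below `max_incomplete_for_cra` (default 0.05 — the
  conventional "under 5%" rule) *and* no substantive or statistical evidence
  (Wald p below `alpha`, default 0.05) that completeness depends on the
  outcome.  The boundary counts as *not* below.  Absent or non-converged
  evidence degrades Q1 to "unknown" and conservatively blocks the
  complete-records route.
* **Q2** (MI benefit): Q1 failed and auxiliaries are declared or confounders
  are incomplete.
* **Q3** (sensitivity required): MNAR suspected, or completeness associated
  with proxies of the incomplete variable.

The 5% and alpha thresholds are judgement calls the engine exposes rather
than hides.  One caveat is attached as a warning, not an automatic reversal:
when MNAR is suspected in exposure/covariates *without* outcome-related
missingness, a complete-records analysis can be unbiased where MI is not —
unverifiable from data alone, so the engine only flags it.  Every verdict
carries its evidence; recommendations replay bit-for-bit.

## Synthetic cohorts: what they emulate, and what not

The `alspac_like_preset` emulates the *structure* of a large birth-cohort
smoking/attainment analysis: a 0–100 attainment outcome (Gaussian linear
model clamped to [0, 100]; default calibration keeps the clamped fraction
under 1% so OLS recovery oracles stay valid), a binary smoking exposure
(marginal prevalence 0.2 — a free parameter, not an empirical value), eight
confounders (4 binary + 4 continuous from a Gaussian copula with latent
correlation 0.3), and adjacent-wave smoking auxiliaries generated as noisy
proxies of the true exposure with sensitivity/specificity 0.80/0.95
(prior wave) and 0.70/0.85 (later wave) plus an IQ-like continuous
auxiliary (r = 0.5 with the outcome).  The auxiliary strengths keep the
imputation-model log-odds within roughly ±5, so an extreme offset δ = 10
saturates imputed values at the "1" level (expit(η+10) ≥ 0.993 for |η| ≤ 5).

Exposure missingness depends on the outcome (−0.05 log-odds per score
point) and maternal education, plus the pass-through `delta_true` on the
true exposure value; the outcome (10% missing, emulating relatively complete
administrative linkage) and five confounders (13% each) depend on fully
observed confounders.  Intercepts are solved numerically (Brent bracketing
on the realized cohort) so that the exposure-missingness proportion is 51%
and the *expected* complete-record proportion — analysis-model variables
only — is 23%, within ±5 points at large n.  The outcome coefficient is a
deliberate compromise: a smooth logistic tilt in the outcome barely biases
the OLS slope of a complete-records analysis (it mainly shifts the
intercept), so the dependence must be steep enough to act as soft truncation
(≈ +0.8-point attenuation of the −10 effect at this setting) yet mild
enough that the missing group's outcome deficit stays well below the true
effect — otherwise the worst-case and δ = 10 analyses would *amplify*
rather than attenuate.

`mnar_exposure_preset` is the clean MNAR bench: exposure missingness depends
*only* on the true exposure value (log-odds a + δ_true·x).  Logistic
selection then implies the odds of exposure among unobserved vs observed
records differ by exactly e^{δ_true} conditional on *any* other variables,
so the pattern-mixture analysis with matched δ is exactly calibrated.  With
outcome-dependent selection added (the full preset), the observed-data
conditional of the exposure is no longer exactly logistic-linear and
matched-δ correction is only approximate — a known property of
pattern-mixture chained equations, not an engine defect.  Under the clean
mechanism the δ = 0 analysis is measurably biased *away* from the null at
these settings: the under-imputed smokers are concentrated on
auxiliary-positive, low-attainment records, so the fitted contrast
overstates the effect; the paired δ response under common random numbers
(≈ +0.29 points from δ = 0 to δ = 1) is the stable signature.

What the cohorts do **not** emulate: real attrition dynamics across a dozen
waves, linkage artifacts, measurement error in the outcome, non-Gaussian
score distributions, or any actual cohort's covariate distributions.
Passing tests therefore demonstrate that the machinery is correct under its
stated mechanisms — not that MI with these settings is unbiased for any
particular real study.

## Simulation scales

Calibration checks use one cohort of n = 20 000.  Recovery studies use
n = 2 000 per replicate: 200 replicates with m = 25 for the MAR benchmark
(Monte-Carlo SE of the mean MI estimate ≈ 0.05 points), 100 replicates with
m = 10 for the matched-δ MNAR benchmark.  These sizes give the bias
assertions ≈ 3-SE resolution while keeping a full run of the suite and the
reproduction script in the minutes range on one CPU.

## Numerical choices and degenerate inputs

* Normal equations solved by Cholesky; a near-zero pivot (relative to the
  largest) flags rank deficiency and adds a 1e-6·scale ridge with a logged
  warning — fail-soft with transparency.
* Logistic Newton iterations are warm-started across cycles within an
  imputation (no RNG involvement, so common-random-number coupling is
  unaffected).
* A variable observed as a single class (binary) or not observed at all is a
  hard error naming the variable, as is a δ on an unknown variable or a
  predictor matrix with self-prediction or missing substantive-model terms
  (imputation/analysis-model compatibility is enforced).
* Zero-residual targets degrade gracefully: the posterior noise scale is 0
  and imputations reproduce the exact fit.
* Tipping-point search walks the δ grid in order and takes the first flip;
  optional bisection refinement assumes the criterion is monotone in δ
  (documented; any single realization is noisy, so the full evaluated trace
  is returned).
* Serialization uses `%.17g` floats, so CSV round-trips are bit-lossless.

## Known limitations

* Pooling targets a single coefficient; no multi-parameter Wald pooling.
* No multivariate-normal joint imputation, no multilevel/survival/propensity
  extensions, no doubly-robust or machine-learning imputation, no formal δ
  elicitation — out of scope by design.
* The logistic posterior is asymptotic-normal, not exact; in tiny samples
  between-imputation variance can be mildly understated.
* δ offsets apply to one variable at a time in the tested workflow.
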