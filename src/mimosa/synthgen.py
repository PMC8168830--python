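"""Synthetic cohort generation with controlled missingness mechanisms.

Generates complete cohorts with a known exposure→outcome effect — a binary
exposure (e.g. adolescent smoking) acting on a bounded 0–100 attainment-style
outcome, confounders, and strongly informative auxiliary variables — and then
imposes MCAR / MAR / MNAR missingness from explicit per-variable logistic
models.  Because the pre-deletion values are retained under a
``simulated-then-deleted`` provenance flag, every downstream stage (diagnosis,
imputation, pooling, sensitivity analysis) can be validated against known
ground truth without access to any real cohort.

The missingness taxonomy is the standard one:

* **MCAR** — the deletion probability is constant (all mechanism coefficients
  zero).
* **MAR** — the deletion probability depends on stored variables but not on
  the deleted value itself given those (``self_coefficient = 0``).
* **MNAR** — ``self_coefficient`` (``delta_true``) is non-zero: missingness
  depends on the value being deleted even conditional on everything else.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
import pandas as pd

from .studytable import StudyTable, StudyTableError, Variable

__all__ = [
    "ConfounderSpec",
    "AuxiliarySpec",
    "SimulationConfig",
    "VariableMechanism",
    "MissingnessMechanism",
    "generate_cohort",
    "impose_missingness",
    "alspac_like_preset",
    "substream",
]


# --------------------------------------------------------------------- RNG
def substream(seed: int, *keys: str) -> np.random.Generator:
    """Named RNG substream: a pure function of (seed, keys).

    Each (operation, variable) pair draws from its own stream so adding a
    variable to a configuration never perturbs the draws of earlier ones.
    """
    digest = hashlib.blake2b("/".join(keys).encode(), digest_size=8).digest()
    key = int.from_bytes(digest, "little")
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), key])))


# ------------------------------------------------------------------- config
@dataclass(frozen=True)
class ConfounderSpec:
    """One confounder: distribution plus its effects on exposure and outcome.

    ``coef_exposure`` acts on the exposure log-odds; ``coef_outcome`` on the
    outcome in score points.  Coefficients apply to the standardized value for
    continuous confounders and to the raw 0/1 value for binary ones.
    """

    name: str
    scale: str  # "binary" | "continuous"
    params: dict  # binary: {"p": ...}; continuous: {"mean": ..., "sd": ...}
    coef_exposure: float = 0.0
    coef_outcome: float = 0.0


@dataclass(frozen=True)
class AuxiliarySpec:
    """One auxiliary variable tied to the exposure or the outcome.

    Binary auxiliaries targeting the exposure are generated as noisy proxies
    with declared sensitivity/specificity (e.g. smoking reported at an
    adjacent wave).  Continuous auxiliaries targeting the outcome are
    generated with a declared correlation.
    """

    name: str
    scale: str  # "binary" | "continuous"
    target: str  # "exposure" | "outcome"
    params: dict  # binary: sensitivity/specificity; continuous: corr/mean/sd


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int
    beta_true: float  # outcome-score points per unit exposure
    confounder_spec: tuple[ConfounderSpec, ...]
    auxiliary_spec: tuple[AuxiliarySpec, ...]
    outcome_noise_sd: float
    seed: int
    outcome_name: str = "attainment_16"
    exposure_name: str = "smoking_14"
    exposure_prevalence: float = 0.2
    outcome_intercept: float = 62.0
    latent_correlation: float = 0.3  # mutual correlation of confounder latents

    def validate(self) -> None:
        if self.n_participants < 1:
            raise StudyTableError("n_participants must be >= 1")
        if self.outcome_noise_sd <= 0:
            raise StudyTableError("outcome_noise_sd must be > 0")
        if not 0.0 < self.exposure_prevalence < 1.0:
            raise StudyTableError("exposure_prevalence must lie in (0, 1)")
        names = (
            [self.outcome_name, self.exposure_name]
            + [c.name for c in self.confounder_spec]
            + [a.name for a in self.auxiliary_spec]
        )
        if len(set(names)) != len(names):
            raise StudyTableError("variable names must be unique")
        for c in self.confounder_spec:
            if c.scale == "binary":
                p = c.params.get("p")
                if p is None or not 0 < p < 1:
                    raise StudyTableError(f"confounder {c.name}: invalid prevalence {p!r}")
            elif c.scale == "continuous":
                if c.params.get("sd", 1.0) <= 0:
                    raise StudyTableError(f"confounder {c.name}: sd must be > 0")
            else:
                raise StudyTableError(f"confounder {c.name}: unsupported scale {c.scale!r}")
        for a in self.auxiliary_spec:
            if a.target not in ("exposure", "outcome"):
                raise StudyTableError(f"auxiliary {a.name}: unknown target {a.target!r}")
            if a.scale == "binary":
                for key in ("sensitivity", "specificity"):
                    v = a.params.get(key)
                    if v is None or not 0 < v <= 1:
                        raise StudyTableError(f"auxiliary {a.name}: invalid {key} {v!r}")
            elif a.scale == "continuous":
                if not -1 < a.params.get("corr", 0.0) < 1:
                    raise StudyTableError(f"auxiliary {a.name}: corr must lie in (-1, 1)")
            else:
                raise StudyTableError(f"auxiliary {a.name}: unsupported scale {a.scale!r}")


# --------------------------------------------------------------- mechanism
@dataclass(frozen=True)
class VariableMechanism:
    """Logistic model for the probability that one variable's cell is missing.

    ``P(missing) = expit(intercept + Σ coefficients[v]·value[v]
    + self_coefficient·own value)``.  A non-zero ``self_coefficient`` makes
    the mechanism MNAR by construction; with it zero and all predictor
    coefficients zero the mechanism is MCAR.
    """

    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    self_coefficient: float = 0.0

    def linear_predictor(self, data: pd.DataFrame, target: str) -> np.ndarray:
        eta = np.full(len(data), float(self.intercept))
        for name, coef in self.coefficients.items():
            if name not in data.columns:
                raise StudyTableError(f"mechanism for {target!r} references unknown variable {name!r}")
            if not np.isfinite(coef):
                raise StudyTableError(f"mechanism for {target!r}: non-finite coefficient on {name!r}")
            eta = eta + coef * data[name].to_numpy(dtype=float)
        if self.self_coefficient != 0.0:
            eta = eta + self.self_coefficient * data[target].to_numpy(dtype=float)
        return eta


@dataclass(frozen=True)
class MissingnessMechanism:
    """Per-variable missingness models, applied independently per cell.

    With ``monotone_dropout`` set, a record missing an earlier target (in
    declaration order) is also missing on all later targets, emulating nested
    wave-on-wave attrition.
    """

    targets: dict[str, VariableMechanism]
    monotone_dropout: bool = False

    @property
    def delta_true(self) -> float:
        """Self-coefficient of the first MNAR target (0 if fully MAR/MCAR)."""
        for mech in self.targets.values():
            if mech.self_coefficient != 0.0:
                return mech.self_coefficient
        return 0.0


# ------------------------------------------------------------ cohort build
def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept a with mean(expit(a + eta)) == target, by bracketing."""
    return brentq(lambda a: expit(a + eta).mean() - target, -40.0, 40.0, xtol=1e-12)


def generate_cohort(config: SimulationConfig) -> StudyTable:
    """Simulate a complete cohort (no missing cells) under ``config``.

    Confounders are drawn from a Gaussian copula with pairwise latent
    correlation ``latent_correlation`` (binary confounders by thresholding at
    their prevalence quantile).  The exposure follows a logistic model on the
    confounders with its intercept solved numerically so the marginal
    prevalence matches ``exposure_prevalence``; the outcome is linear in
    exposure and confounders with coefficient ``beta_true`` on the exposure
    plus Gaussian noise, clamped to [0, 100].
    """
    config.validate()
    n = config.n_participants
    seed = config.seed
    from scipy.stats import norm

    k = len(config.confounder_spec)
    rng_conf = substream(seed, "confounders")
    if k:
        rho = config.latent_correlation
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        z = rng_conf.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    else:
        z = np.empty((n, 0))

    columns: dict[str, np.ndarray] = {}
    standardized: dict[str, np.ndarray] = {}
    for j, spec in enumerate(config.confounder_spec):
        if spec.scale == "binary":
            x = (z[:, j] < norm.ppf(spec.params["p"])).astype(float)
            standardized[spec.name] = x  # raw 0/1 enters the linear predictors
        else:
            x = spec.params.get("mean", 0.0) + spec.params.get("sd", 1.0) * z[:, j]
            standardized[spec.name] = z[:, j]
        columns[spec.name] = x

    # exposure: logistic on confounders, intercept solved to the target prevalence
    eta = np.zeros(n)
    for spec in config.confounder_spec:
        eta += spec.coef_exposure * standardized[spec.name]
    rng_exp = substream(seed, "exposure")
    a = _solve_intercept(eta, config.exposure_prevalence) if n > 1 else 0.0
    exposure = (rng_exp.random(n) < expit(a + eta)).astype(float)
    columns[config.exposure_name] = exposure

    # outcome: linear model with Gaussian noise, clamped to the score range
    rng_out = substream(seed, "outcome")
    y = config.outcome_intercept + config.beta_true * exposure
    for spec in config.confounder_spec:
        y = y + spec.coef_outcome * standardized[spec.name]
    y = y + config.outcome_noise_sd * rng_out.standard_normal(n)
    y_std = (y - y.mean()) / y.std() if n > 1 and y.std() > 0 else np.zeros(n)
    columns[config.outcome_name] = np.clip(y, 0.0, 100.0)

    for spec in config.auxiliary_spec:
        rng_aux = substream(seed, "auxiliary", spec.name)
        if spec.scale == "binary":
            anchor = exposure if spec.target == "exposure" else (y_std > 0).astype(float)
            p1 = np.where(
                anchor == 1.0,
                spec.params["sensitivity"],
                1.0 - spec.params["specificity"],
            )
            columns[spec.name] = (rng_aux.random(n) < p1).astype(float)
        else:
            r = spec.params.get("corr", 0.5)
            base = y_std if spec.target == "outcome" else exposure - exposure.mean()
            base = base / base.std() if n > 1 and base.std() > 0 else np.zeros(n)
            latent = r * base + np.sqrt(1 - r**2) * rng_aux.standard_normal(n)
            columns[spec.name] = spec.params.get("mean", 0.0) + spec.params.get("sd", 1.0) * latent

    variables = [
        Variable(config.outcome_name, "outcome", "continuous"),
        Variable(config.exposure_name, "exposure", "binary"),
    ]
    variables += [Variable(c.name, "confounder", c.scale) for c in config.confounder_spec]
    variables += [Variable(a.name, "auxiliary", a.scale) for a in config.auxiliary_spec]
    order = [v.name for v in variables]
    data = pd.DataFrame({name: columns[name] for name in order})
    return StudyTable(data, variables, truth=data.copy())


# --------------------------------------------------------------- deletion
def impose_missingness(
    table: StudyTable, mechanism: MissingnessMechanism, seed: int
) -> StudyTable:
    """Delete cells per the mechanism's logistic models, retaining the truth.

    Each targeted cell is deleted independently with probability
    ``expit(intercept + Σ coef·predictor + self_coefficient·own value)``
    evaluated on the complete table.  Deleted values stay available through
    the returned table's ``truth`` attribute under the
    ``simulated-then-deleted`` provenance flag.
    """
    if table.data.isna().any().any():
        raise StudyTableError("impose_missingness requires a complete table")
    complete = table.data
    deleted_masks: dict[str, np.ndarray] = {}
    for target, mech in mechanism.targets.items():
        if target not in complete.columns:
            raise StudyTableError(f"mechanism targets unknown variable {target!r}")
        eta = mech.linear_predictor(complete, target)
        p = expit(eta)
        rng = substream(seed, "missingness", target)
        deleted_masks[target] = rng.random(len(complete)) < p

    if mechanism.monotone_dropout:
        carried = np.zeros(len(complete), dtype=bool)
        for target in mechanism.targets:
            carried |= deleted_masks[target]
            deleted_masks[target] = carried.copy()

    data = complete.copy()
    for target, drop in deleted_masks.items():
        data.loc[drop, target] = np.nan
    return StudyTable(data, list(table.variables.values()), truth=complete.copy())


# ------------------------------------------------------------------ preset
def _preset_config(n: int, seed: int, beta_true: float = -10.0) -> SimulationConfig:
    confounders = (
        ConfounderSpec("sex", "binary", {"p": 0.49}, coef_exposure=0.10, coef_outcome=1.5),
        ConfounderSpec("mat_smoking", "binary", {"p": 0.25}, coef_exposure=0.50, coef_outcome=-2.0),
        ConfounderSpec("pat_smoking", "binary", {"p": 0.30}, coef_exposure=0.40, coef_outcome=-1.0),
        ConfounderSpec("mat_education_high", "binary", {"p": 0.35}, coef_exposure=-0.40, coef_outcome=4.0),
        ConfounderSpec("pat_education_score", "continuous", {"mean": 0.0, "sd": 1.0}, coef_exposure=-0.20, coef_outcome=2.0),
        ConfounderSpec("parity", "continuous", {"mean": 1.2, "sd": 1.0}, coef_exposure=0.10, coef_outcome=-0.5),
        ConfounderSpec("behaviour_81m", "continuous", {"mean": 8.0, "sd": 4.0}, coef_exposure=0.30, coef_outcome=-2.0),
        ConfounderSpec("attainment_11", "continuous", {"mean": 55.0, "sd": 15.0}, coef_exposure=-0.40, coef_outcome=8.0),
    )
    auxiliaries = (
        AuxiliarySpec("smoking_13", "binary", "exposure", {"sensitivity": 0.80, "specificity": 0.95}),
        AuxiliarySpec("smoking_15", "binary", "exposure", {"sensitivity": 0.70, "specificity": 0.85}),
        AuxiliarySpec("iq_8", "continuous", "outcome", {"corr": 0.5, "mean": 100.0, "sd": 15.0}),
    )
    return SimulationConfig(
        n_participants=n,
        beta_true=beta_true,
        confounder_spec=confounders,
        auxiliary_spec=auxiliaries,
        outcome_noise_sd=11.0,
        seed=seed,
    )


# Marginal missingness targets for the non-exposure incomplete variables; the
# exposure target and the complete-record target mirror the case-study facts
# (about half the exposure missing, under a quarter of records complete).
_PRESET_MARGINALS = {
    "attainment_16": 0.10,
    "parity": 0.13,
    "pat_smoking": 0.13,
    "pat_education_score": 0.13,
    "behaviour_81m": 0.13,
    "attainment_11": 0.13,
}


# Missingness models for the non-exposure incomplete variables: each depends
# on fully observed confounders (plus, for prior attainment, mildly on the
# outcome), so they are MAR by construction.
_PRESET_OTHER_COEFS: dict[str, dict[str, float]] = {
    "attainment_16": {"mat_education_high": -0.30, "mat_smoking": 0.30},
    "parity": {"mat_education_high": -0.20},
    "pat_smoking": {"mat_smoking": 0.40},
    "pat_education_score": {"mat_education_high": -0.30},
    "behaviour_81m": {"sex": 0.20},
    "attainment_11": {"mat_education_high": -0.20, "attainment_16": -0.020},
}


def _build_preset_mechanism(
    complete: StudyTable,
    config: SimulationConfig,
    exposure_coefs: dict[str, float],
    delta_true: float,
    exposure_missing_target: float,
    complete_record_target: float,
) -> MissingnessMechanism:
    """Solve mechanism intercepts against the realized complete cohort.

    The exposure intercept is solved so its marginal missingness matches the
    target; a shared offset on the remaining intercepts is then solved so the
    *expected* complete-record proportion (analysis-model variables only)
    matches its target — deletion events are independent Bernoulli per cell
    given the row, so the expectation is exact and no sampling is involved.
    """
    cdata = complete.data
    n = len(cdata)
    eta_exp = np.zeros(n)
    for name, coef in exposure_coefs.items():
        eta_exp += coef * cdata[name].to_numpy(dtype=float)
    eta_exp += delta_true * cdata[config.exposure_name].to_numpy(dtype=float)
    a_exp = _solve_intercept(eta_exp, exposure_missing_target)

    etas: dict[str, np.ndarray] = {}
    bases: dict[str, float] = {}
    for target, coefs in _PRESET_OTHER_COEFS.items():
        eta = np.zeros(n)
        for name, coef in coefs.items():
            eta += coef * cdata[name].to_numpy(dtype=float)
        etas[target] = eta
        bases[target] = _solve_intercept(eta, _PRESET_MARGINALS[target])

    p_exp = expit(a_exp + eta_exp)

    def expected_complete(c: float) -> float:
        keep = 1.0 - p_exp
        for target in _PRESET_OTHER_COEFS:
            keep = keep * (1.0 - expit(bases[target] + c + etas[target]))
        return keep.mean()

    c_star = brentq(
        lambda c: expected_complete(c) - complete_record_target, -10.0, 10.0, xtol=1e-10
    )
    targets = {
        config.exposure_name: VariableMechanism(
            intercept=a_exp, coefficients=exposure_coefs, self_coefficient=delta_true
        )
    }
    for target, coefs in _PRESET_OTHER_COEFS.items():
        targets[target] = VariableMechanism(
            intercept=bases[target] + c_star, coefficients=coefs
        )
    return MissingnessMechanism(targets=targets)


def alspac_like_preset(
    n: int,
    seed: int,
    delta_true: float = 0.0,
    beta_true: float = -10.0,
    exposure_missing_target: float = 0.51,
    complete_record_target: float = 0.23,
) -> tuple[StudyTable, SimulationConfig, MissingnessMechanism]:
    """Cohort emulating the structure of a birth-cohort smoking/attainment study.

    A binary smoking exposure with roughly half its values missing, a bounded
    attainment outcome, eight confounders (four binary, four continuous, with
    moderate mutual correlation) and strongly informative adjacent-wave
    smoking auxiliaries.  Exposure missingness depends on the outcome and on
    maternal education (and, when ``delta_true != 0``, on the true smoking
    value itself — the MNAR knob); the remaining incomplete variables depend
    on fully observed confounders.  Intercepts are solved numerically so that,
    in expectation, the exposure-missingness proportion and the
    complete-record proportion match their targets.
    """
    if n < 200:
        raise StudyTableError("preset requires n >= 200")
    config = _preset_config(n, seed, beta_true=beta_true)
    complete = generate_cohort(config)
    mechanism = _build_preset_mechanism(
        complete,
        config,
        exposure_coefs={"attainment_16": -0.05, "mat_education_high": -0.30},
        delta_true=delta_true,
        exposure_missing_target=exposure_missing_target,
        complete_record_target=complete_record_target,
    )
    observed = impose_missingness(complete, mechanism, seed=seed)
    return observed, config, mechanism


def mnar_exposure_preset(
    n: int,
    seed: int,
    delta_true: float = 1.0,
    beta_true: float = -10.0,
    exposure_missing_target: float = 0.50,
    complete_record_target: float = 0.23,
) -> tuple[StudyTable, SimulationConfig, MissingnessMechanism]:
    """Preset cohort whose exposure missingness depends *only* on its own value.

    The clean MNAR bench: with selection log-odds ``a + delta_true·x`` the
    odds of exposure among unobserved vs observed records differ by exactly
    ``exp(delta_true)`` conditional on any other variables, so a
    pattern-mixture analysis with offset δ = ``delta_true`` is exactly
    calibrated and should recover the true effect, while the δ = 0 analysis
    under-imputes the "1" level and attenuates it.  The remaining variables
    keep the MAR mechanisms of :func:`alspac_like_preset`.
    """
    if n < 200:
        raise StudyTableError("preset requires n >= 200")
    config = _preset_config(n, seed, beta_true=beta_true)
    complete = generate_cohort(config)
    mechanism = _build_preset_mechanism(
        complete,
        config,
        exposure_coefs={},
        delta_true=delta_true,
        exposure_missing_target=exposure_missing_target,
        complete_record_target=complete_record_target,
    )
    observed = impose_missingness(complete, mechanism, seed=seed)
    return observed, config, mechanism
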