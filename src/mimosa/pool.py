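"""Substantive-model fitting and Rubin's-rules pooling.

The substantive model is a linear regression of a continuous outcome on a
binary exposure adjusted for confounders; the estimand is the exposure
coefficient (adjusted mean difference, in outcome-score points).  The model
is fitted by OLS to each completed data set and the m estimates are combined
with Rubin's rules:

    Q̄ = mean(Q̂_i)            pooled estimate
    Ū = mean(U_i)             within-imputation variance
    B = var(Q̂_i)              between-imputation variance (sample variance)
    T = Ū + (1 + 1/m)·B       total variance
    riv = (1 + 1/m)·B / Ū     relative increase in variance

Degrees of freedom use the Barnard–Rubin small-sample adjustment by default
(the classic large-sample (m−1)(1 + 1/riv)² form is available via
``df_method="classic"`` for cross-checking against other software), and the
fraction of missing information is fmi = (riv + 2/(df+3)) / (1 + riv).
Confidence intervals and p-values use the t reference with the pooled df.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .studytable import StudyTable, StudyTableError

__all__ = [
    "SubstantiveModelSpec",
    "ImputationFit",
    "FitResult",
    "PooledResult",
    "fit_substantive",
    "fit_stack",
    "fit_complete_records",
    "pool_rubin",
]


@dataclass(frozen=True)
class SubstantiveModelSpec:
    outcome: str
    exposure: str
    confounders: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [self.outcome, self.exposure, *self.confounders]
        if len(set(names)) != len(names):
            raise StudyTableError("outcome, exposure and confounders must be disjoint")

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.outcome, self.exposure, *self.confounders)

    @classmethod
    def from_table(cls, table: StudyTable) -> "SubstantiveModelSpec":
        return cls(table.outcome, table.exposure, tuple(table.confounders))


@dataclass(frozen=True)
class ImputationFit:
    """One completed-data OLS fit: the exposure estimate and its variance."""

    estimate: float  # Q̂_i
    variance: float  # U_i = SE_i²
    params: dict[str, float]
    n: int
    df_complete: int  # n − p: complete-data residual df


@dataclass
class FitResult:
    fits: list[ImputationFit] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.fits)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([f.estimate for f in self.fits])

    @property
    def variances(self) -> np.ndarray:
        return np.array([f.variance for f in self.fits])


@dataclass
class PooledResult:
    """Rubin's-rules quantities for the exposure coefficient."""

    estimate: float  # Q̄
    within_variance: float  # Ū
    between_variance: float  # B
    total_variance: float  # T
    df: float
    ci_low: float
    ci_high: float
    p: float
    riv: float
    fmi: float
    m: int
    n: int
    method: str = "multiple_imputation"
    df_method: str = "barnard_rubin"
    per_imputation: list[ImputationFit] = field(default_factory=list)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))

    def ci_includes(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "within_variance": self.within_variance,
            "between_variance": self.between_variance,
            "total_variance": self.total_variance,
            "df": self.df,
            "df_method": self.df_method,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "riv": self.riv,
            "fmi": self.fmi,
            "m": self.m,
            "n": self.n,
            "per_imputation": [
                {"estimate": f.estimate, "variance": f.variance, "n": f.n}
                for f in self.per_imputation
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ----------------------------------------------------------------- fitting
def _design(df: pd.DataFrame, model: SubstantiveModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    for name in model.variables:
        if name not in df.columns:
            raise StudyTableError(f"model variable {name!r} not in table")
    y = df[model.outcome].astype(float)
    X = df[[model.exposure, *model.confounders]]
    # non-numeric confounders (declared categorical) enter as treatment dummies
    X = pd.get_dummies(X, drop_first=True, dtype=float).astype(float)
    X = sm.add_constant(X, has_constant="add")
    return y, X


def fit_substantive(completed: pd.DataFrame, model: SubstantiveModelSpec) -> ImputationFit:
    """OLS fit of the substantive model to one completed data set."""
    if completed[list(model.variables)].isna().any().any():
        raise StudyTableError("fit_substantive requires complete data for model variables")
    y, X = _design(completed, model)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(corr) > 1 else ("const", "?")
        raise StudyTableError(
            f"collinear design (rank {rank} < {X.shape[1]}); "
            f"most aliased pair: {worst[0]!r} ~ {worst[1]!r}"
        )
    fit = sm.OLS(y, X).fit()
    est = float(fit.params[model.exposure])
    se = float(fit.bse[model.exposure])
    return ImputationFit(
        estimate=est,
        variance=se**2,
        params={k: float(v) for k, v in fit.params.items()},
        n=int(fit.nobs),
        df_complete=int(fit.df_resid),
    )


def fit_stack(stack, model: SubstantiveModelSpec) -> FitResult:
    """Fit the substantive model to every completed copy of an ImputedStack."""
    result = FitResult()
    for i in range(stack.m):
        result.fits.append(fit_substantive(stack.completed(i), model))
    ns = {f.n for f in result.fits}
    if len(ns) != 1:
        raise StudyTableError(f"inconsistent n across imputations: {sorted(ns)}")
    return result


def fit_complete_records(table: StudyTable, model: SubstantiveModelSpec) -> PooledResult:
    """OLS on complete records only, shaped like a PooledResult.

    Between-imputation variance is zero by construction (single fit); the CI
    uses the t reference with the complete-data residual df.
    """
    complete = table.is_complete_record()
    n_complete = int(complete.sum())
    needed = len(model.confounders) + 3
    if n_complete < needed:
        raise StudyTableError(
            f"too few complete records ({n_complete}) for "
            f"{len(model.confounders)} confounders (need >= {needed})"
        )
    fit = fit_substantive(table.data[complete].reset_index(drop=True), model)
    se = np.sqrt(fit.variance)
    df = fit.df_complete
    tcrit = stats.t.ppf(0.975, df)
    tval = fit.estimate / se if se > 0 else np.inf
    return PooledResult(
        estimate=fit.estimate,
        within_variance=fit.variance,
        between_variance=0.0,
        total_variance=fit.variance,
        df=float(df),
        ci_low=fit.estimate - tcrit * se,
        ci_high=fit.estimate + tcrit * se,
        p=float(2 * stats.t.sf(abs(tval), df)),
        riv=0.0,
        fmi=0.0,
        m=1,
        n=fit.n,
        method="complete_records",
        df_method="complete_data",
        per_imputation=[fit],
    )


# ----------------------------------------------------------------- pooling
def pool_rubin(
    fits: FitResult,
    df_complete: int | None = None,
    df_method: str = "barnard_rubin",
) -> PooledResult:
    """Combine per-imputation estimates with Rubin's rules.

    ``df_complete`` is the complete-data residual degrees of freedom used by
    the Barnard–Rubin adjustment; it defaults to the value recorded in the
    fits.  With ``df_method="classic"`` the large-sample form
    (m−1)(1 + 1/riv)² is used instead.
    """
    m = fits.m
    if m < 2:
        raise StudyTableError("pooling requires m >= 2 (B is undefined otherwise)")
    q = fits.estimates
    u = fits.variances
    if np.any(u <= 0):
        raise StudyTableError("within-imputation variances must be positive")
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    t_total = ubar + (1.0 + 1.0 / m) * b
    riv = (1.0 + 1.0 / m) * b / ubar
    lam = (1.0 + 1.0 / m) * b / t_total  # proportion of variance due to missingness

    if df_complete is None:
        df_complete = fits.fits[0].df_complete
    if b == 0.0:
        df = float(df_complete)
    else:
        df_classic = (m - 1) * (1.0 + 1.0 / riv) ** 2
        if df_method == "classic":
            df = df_classic
        elif df_method == "barnard_rubin":
            df_obs = (
                (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
            )
            df = 1.0 / (1.0 / df_classic + 1.0 / df_obs)
        else:
            raise StudyTableError(f"unknown df_method {df_method!r}")
    fmi = (riv + 2.0 / (df + 3.0)) / (1.0 + riv)

    se = np.sqrt(t_total)
    tcrit = stats.t.ppf(0.975, df)
    tval = qbar / se if se > 0 else np.inf
    return PooledResult(
        estimate=qbar,
        within_variance=ubar,
        between_variance=b,
        total_variance=t_total,
        df=float(df),
        ci_low=qbar - tcrit * se,
        ci_high=qbar + tcrit * se,
        p=float(2 * stats.t.sf(abs(tval), df)),
        riv=float(riv),
        fmi=float(fmi),
        m=m,
        n=fits.fits[0].n,
        df_method=df_method,
        per_imputation=list(fits.fits),
    )
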