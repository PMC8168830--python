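"""Fully-conditional-specification (chained equations) multiple imputation.

The engine iterates over the incomplete variables, regressing each on the
*current* completed values of its declared predictors and redrawing its
missing cells from the resulting predictive distribution.  All draws are
*proper*: regression parameters are themselves drawn from their (approximate)
posterior before values are imputed, so between-imputation variance reflects
parameter uncertainty.

Column models
-------------
``bayes_linear``
    Draws the residual variance from its scaled inverse-chi-square posterior
    and the coefficients from their conditional normal posterior, then imputes
    linear predictor + δ + Gaussian noise.
``bayes_logistic``
    Maximum-likelihood logistic fit; coefficient vector drawn from the
    asymptotic normal approximation to the posterior; missing cells imputed
    Bernoulli(expit(linear predictor + δ)).
``pmm``
    Predictive mean matching: each missing cell receives the observed value
    of one of the ``k`` donors whose predicted mean is nearest to the missing
    row's predicted mean (type-1 matching; ties broken by lowest row index).
``polytomous``
    Categorical targets with more than two levels: a sequence of one-vs-rest
    logistic draws normalized to a single categorical draw.

δ offsets implement pattern-mixture sensitivity analysis: for a flagged
variable the offset is added to the linear predictor (binary targets,
log-odds units) or to the imputed values (continuous targets, outcome units)
at every cycle, and applies only while imputing that variable — observed
cells are never touched.

Binary and categorical draws compare a uniform variate against the drawn
probability, and every column model consumes an identical number of random
variates regardless of δ, so runs that share a seed are coupled by common
random numbers: differences between δ settings are attributable to δ, not to
Monte-Carlo noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve, solve_triangular
from scipy.special import expit

from .studytable import StudyTable, StudyTableError, Variable
from .synthgen import substream

__all__ = [
    "ImputationSpec",
    "ImputedStack",
    "DegenerateTargetError",
    "default_spec",
    "initialize",
    "impute_bayes_linear",
    "impute_bayes_logistic",
    "impute_pmm",
    "run_chained",
]


class DegenerateTargetError(ValueError):
    """Target variable cannot be modelled (one class, or nothing observed)."""


# ---------------------------------------------------------------- spec
@dataclass(frozen=True)
class ImputationSpec:
    """Full specification of one chained-equations run.

    ``predictors`` maps each imputed variable to its predictor set; it must
    contain every substantive-model variable (compatibility of the imputation
    and analysis models), may contain auxiliaries, and never contains the
    variable itself.  ``offsets`` maps variables to δ: log-odds units for
    binary targets, outcome units for continuous targets.
    """

    column_models: dict[str, str]  # variable -> bayes_linear|bayes_logistic|pmm|polytomous
    predictors: dict[str, tuple[str, ...]]
    m: int = 25
    cycles: int = 10
    offsets: dict[str, float] = field(default_factory=dict)
    pmm_donors: int = 5
    seed: int = 0
    substantive_variables: tuple[str, ...] = ()

    def validate(self, table: StudyTable) -> None:
        if self.m < 2:
            raise StudyTableError("m must be >= 2 (between-imputation variance needs it)")
        if self.cycles < 1 or self.pmm_donors < 1:
            raise StudyTableError("cycles and pmm_donors must be >= 1")
        known = set(table.variables)
        incomplete = [v for v in table.variables if table.data[v].isna().any()]
        for var in incomplete:
            if var not in self.column_models:
                raise StudyTableError(f"incomplete variable {var!r} has no column model")
            preds = self.predictors.get(var, ())
            if var in preds:
                raise StudyTableError(f"{var!r} cannot predict itself")
            unknown = set(preds) - known
            if unknown:
                raise StudyTableError(f"{var!r}: unknown predictors {sorted(unknown)}")
            required = set(self.substantive_variables) - {var}
            missing = required - set(preds)
            if missing:
                raise StudyTableError(
                    f"{var!r}: imputation model omits substantive-model "
                    f"variables {sorted(missing)} (incompatible models)"
                )
        for var, method in self.column_models.items():
            scale = table.variables[var].scale
            ok = {
                "bayes_linear": scale == "continuous",
                "bayes_logistic": scale == "binary",
                "pmm": scale == "continuous",
                "polytomous": scale == "categorical",
            }.get(method)
            if ok is None:
                raise StudyTableError(f"{var!r}: unknown column model {method!r}")
            if not ok:
                raise StudyTableError(f"{var!r}: column model {method!r} does not fit scale {scale!r}")
        for var in self.offsets:
            if var not in known:
                raise StudyTableError(f"offset on unknown variable {var!r}")


def default_spec(
    table: StudyTable,
    m: int = 25,
    cycles: int = 10,
    seed: int = 0,
    offsets: dict[str, float] | None = None,
    continuous_method: str = "bayes_linear",
) -> ImputationSpec:
    """Spec with every incomplete variable regressed on all other variables.

    Auxiliaries are included as predictors (that is their purpose), and the
    predictor sets automatically satisfy substantive-model compatibility.
    """
    incomplete = [v for v in table.variables if table.data[v].isna().any()]
    models: dict[str, str] = {}
    predictors: dict[str, tuple[str, ...]] = {}
    for var in incomplete:
        scale = table.variables[var].scale
        if scale == "continuous":
            models[var] = continuous_method
        elif scale == "binary":
            models[var] = "bayes_logistic"
        else:
            models[var] = "polytomous"
        predictors[var] = tuple(v for v in table.variables if v != var)
    return ImputationSpec(
        column_models=models,
        predictors=predictors,
        m=m,
        cycles=cycles,
        offsets=dict(offsets or {}),
        seed=seed,
        substantive_variables=tuple(table.analysis_variables),
    )


# ------------------------------------------------------------- primitives
def _check_finite(name: str, *arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.isfinite(a).all():
            raise StudyTableError(f"{name}: non-finite values in input")


def _lin_solve(X: np.ndarray, y: np.ndarray, warnings: list[str] | None = None):
    """Least squares via the normal equations with a ridge fall-back.

    Returns (beta_hat, upper-Cholesky factor R with XtX = R'R)."""
    XtX = X.T @ X
    Xty = X.T @ y
    deficient = False
    try:
        c, low = cho_factor(XtX, lower=False)
        diag = np.abs(np.diag(c))
        # near-zero Cholesky pivot => numerically singular normal equations
        deficient = diag.min() <= np.sqrt(np.finfo(float).eps) * diag.max()
    except LinAlgError:
        deficient = True
    if deficient:
        scale = max(float(np.trace(XtX)) / XtX.shape[0], 1.0)
        XtX = XtX + 1e-6 * scale * np.eye(XtX.shape[0])
        c, low = cho_factor(XtX, lower=False)
        if warnings is not None:
            warnings.append("rank-deficient design: ridge 1e-6 applied")
    beta_hat = cho_solve((c, low), Xty)
    return beta_hat, c


def impute_bayes_linear(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    delta: float,
    rng: np.random.Generator,
    warnings: list[str] | None = None,
) -> np.ndarray:
    """Proper Bayesian linear imputation with an additive offset δ.

    Design matrices are used exactly as supplied (include an intercept column
    if one is wanted).  Requires at least p + 2 observed rows.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    X_obs = np.atleast_2d(np.asarray(X_obs, dtype=float))
    X_mis = np.atleast_2d(np.asarray(X_mis, dtype=float))
    _check_finite("impute_bayes_linear", y_obs, X_obs, X_mis)
    n, p = X_obs.shape
    if n < p + 2:
        raise StudyTableError(f"impute_bayes_linear: needs >= {p + 2} observed rows, got {n}")
    beta_hat, R = _lin_solve(X_obs, y_obs, warnings)
    resid = y_obs - X_obs @ beta_hat
    ss = float(resid @ resid)
    df = max(n - p, 1)
    sigma2 = ss / rng.chisquare(df)
    z = rng.standard_normal(p)
    beta = beta_hat + np.sqrt(sigma2) * solve_triangular(R, z, lower=False)
    noise = np.sqrt(sigma2) * rng.standard_normal(X_mis.shape[0])
    # δ added last so runs sharing a seed differ by exactly δ elementwise
    return (X_mis @ beta + noise) + delta


def _logistic_mle(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
    ridge: float = 1e-6,
    max_iter: int = 30,
    tol: float = 1e-8,
):
    """Newton–Raphson logistic MLE; returns (beta, upper-Cholesky of the Hessian).

    A tiny ridge keeps the Hessian invertible; separation is detected by
    runaway coefficients and handled by a stronger, flagged penalty.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    R = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        c, low = cho_factor(H, lower=False)
        step = cho_solve((c, low), grad)
        beta += step
        R = c
        if np.max(np.abs(step)) < tol:
            break
    return beta, R


def impute_bayes_logistic(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    delta: float,
    rng: np.random.Generator,
    warnings: list[str] | None = None,
    beta0: np.ndarray | None = None,
    return_eta: bool = False,
):
    """Proper logistic imputation: Bernoulli(expit(linear predictor + δ)).

    The coefficient vector is drawn from the asymptotic normal approximation
    to the posterior at the MLE.  Separation triggers a penalized refit with a
    recorded warning.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    X_obs = np.atleast_2d(np.asarray(X_obs, dtype=float))
    X_mis = np.atleast_2d(np.asarray(X_mis, dtype=float))
    _check_finite("impute_bayes_logistic", y_obs, X_obs, X_mis)
    classes = np.unique(y_obs)
    if classes.size < 2:
        raise DegenerateTargetError("impute_bayes_logistic: only one class observed")
    beta, R = _logistic_mle(X_obs, y_obs, beta0=beta0)
    if np.max(np.abs(beta)) > 12.0:
        beta, R = _logistic_mle(X_obs, y_obs, ridge=1.0)
        if warnings is not None:
            warnings.append("possible separation in logistic fit: penalized fall-back")
    z = rng.standard_normal(len(beta))
    beta_draw = beta + solve_triangular(R, z, lower=False)
    eta = X_mis @ beta_draw
    p_mis = expit(eta + delta)
    u = rng.random(X_mis.shape[0])
    imputed = (u < p_mis).astype(float)
    if return_eta:
        return imputed, beta, eta
    return imputed


def impute_pmm(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
    delta: float = 0.0,
    warnings: list[str] | None = None,
) -> np.ndarray:
    """Predictive mean matching with k donors (type-1 matching).

    Observed rows are scored with the least-squares coefficients, missing rows
    with a posterior draw; each missing row copies the observed value of one
    uniformly chosen donor among the k nearest predicted means (ties broken
    by lowest row index).  A non-zero δ shifts the missing rows' predicted
    means before matching, so imputed values remain donor-pool members.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    X_obs = np.atleast_2d(np.asarray(X_obs, dtype=float))
    X_mis = np.atleast_2d(np.asarray(X_mis, dtype=float))
    _check_finite("impute_pmm", y_obs, X_obs, X_mis)
    n, p = X_obs.shape
    if k > n:
        raise StudyTableError(f"impute_pmm: k={k} exceeds observed count {n}")
    beta_hat, R = _lin_solve(X_obs, y_obs, warnings)
    resid = y_obs - X_obs @ beta_hat
    sigma2 = float(resid @ resid) / rng.chisquare(max(n - p, 1))
    z = rng.standard_normal(p)
    beta_draw = beta_hat + np.sqrt(sigma2) * solve_triangular(R, z, lower=False)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_draw + delta
    n_mis = X_mis.shape[0]
    donors = np.empty(n_mis, dtype=np.int64)
    pick = rng.integers(0, k, size=n_mis)
    block = max(1, int(2_000_000 // max(n, 1)))  # bound the distance-matrix memory
    for start in range(0, n_mis, block):
        stop = min(start + block, n_mis)
        d = np.abs(yhat_obs[None, :] - yhat_mis[start:stop, None])
        nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
        donors[start:stop] = nearest[np.arange(stop - start), pick[start:stop]]
    return y_obs[donors]


# ------------------------------------------------------------- initialize
def _start_fill(
    data: pd.DataFrame, variables: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    filled = data.copy()
    for var in variables:
        col = data[var]
        mis = col.isna()
        if not mis.any():
            continue
        pool = col.dropna().to_numpy()
        if pool.size == 0:
            raise DegenerateTargetError(f"variable {var!r} has no observed values")
        filled.loc[mis, var] = rng.choice(pool, size=int(mis.sum()), replace=True)
    return filled


def initialize(table: StudyTable, seed: int) -> pd.DataFrame:
    """Fill every missing cell with a uniform draw from its observed values."""
    if not table.data.isna().any().any():
        raise StudyTableError("initialize requires at least one missing cell")
    rng = substream(seed, "initialize")
    return _start_fill(table.data, list(table.variables), rng)


# ------------------------------------------------------------ chained run
@dataclass
class ImputedStack:
    """m completed copies of a study table plus full imputation provenance."""

    tables: list[pd.DataFrame]
    imputed_mask: pd.DataFrame  # True where a cell was imputed
    spec: ImputationSpec
    variables: list[Variable]
    substream_ids: list[str]
    warnings: dict[str, int] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.tables)

    def completed(self, i: int) -> pd.DataFrame:
        return self.tables[i]

    # ------------------------------------------------------------------ I/O
    def to_dir(self, path: str | Path) -> None:
        """One CSV per imputation plus a JSON manifest; round-trip lossless."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(self.tables):
            t.to_csv(path / f"imputation_{i:03d}.csv", index=False, float_format="%.17g")
        manifest = {
            "m": self.m,
            "spec": {
                "column_models": self.spec.column_models,
                "predictors": {k: list(v) for k, v in self.spec.predictors.items()},
                "m": self.spec.m,
                "cycles": self.spec.cycles,
                "offsets": self.spec.offsets,
                "pmm_donors": self.spec.pmm_donors,
                "seed": self.spec.seed,
                "substantive_variables": list(self.spec.substantive_variables),
            },
            "variables": [
                {"name": v.name, "role": v.role, "scale": v.scale,
                 "levels": list(v.levels) if v.levels else None}
                for v in self.variables
            ],
            "substream_ids": self.substream_ids,
            "warnings": self.warnings,
            "imputed_cells": {
                var: self.imputed_mask.index[self.imputed_mask[var]].tolist()
                for var in self.imputed_mask.columns
                if self.imputed_mask[var].any()
            },
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ImputedStack":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        s = manifest["spec"]
        spec = ImputationSpec(
            column_models=s["column_models"],
            predictors={k: tuple(v) for k, v in s["predictors"].items()},
            m=s["m"],
            cycles=s["cycles"],
            offsets=s["offsets"],
            pmm_donors=s["pmm_donors"],
            seed=s["seed"],
            substantive_variables=tuple(s["substantive_variables"]),
        )
        variables = [
            Variable(v["name"], v["role"], v["scale"],
                     tuple(v["levels"]) if v["levels"] else None)
            for v in manifest["variables"]
        ]
        numeric = [v.name for v in variables if v.scale in ("continuous", "binary")]
        tables = []
        for i in range(manifest["m"]):
            t = pd.read_csv(path / f"imputation_{i:03d}.csv")
            t[numeric] = t[numeric].astype(float)
            tables.append(t)
        mask = pd.DataFrame(False, index=range(len(tables[0])), columns=tables[0].columns)
        for var, idx in manifest["imputed_cells"].items():
            mask.loc[idx, var] = True
        return cls(
            tables=tables,
            imputed_mask=mask,
            spec=spec,
            variables=variables,
            substream_ids=manifest["substream_ids"],
            warnings={k: int(v) for k, v in manifest["warnings"].items()},
        )


def _visit_order(table: StudyTable) -> list[str]:
    """Incomplete variables sorted by ascending missingness (most-missing
    last), ties by declaration order."""
    counts = table.data.isna().sum()
    declared = {name: i for i, name in enumerate(table.variables)}
    incomplete = [v for v in table.variables if counts[v] > 0]
    return sorted(incomplete, key=lambda v: (counts[v], declared[v]))


def _design_columns(variables: dict[str, Variable], predictors: Sequence[str]) -> list[tuple[str, object]]:
    """Expand predictors into design columns: (name, level-or-None)."""
    cols: list[tuple[str, object]] = []
    for p in predictors:
        v = variables[p]
        if v.scale == "categorical":
            cols.extend((p, lvl) for lvl in v.levels[1:])  # first level is reference
        else:
            cols.append((p, None))
    return cols


def run_chained(table: StudyTable, spec: ImputationSpec) -> ImputedStack:
    """Run the chained-equations engine: m independent imputations.

    Each imputation starts from a fresh random fill and performs
    ``spec.cycles`` sweeps over the incomplete variables in the fixed visit
    order, regressing each on the current completed values of its predictors
    and redrawing its missing cells.  Fully reproducible from ``spec.seed``;
    observed cells are passed through bit-exactly.
    """
    spec.validate(table)
    if not table.data.isna().any().any():
        raise StudyTableError("run_chained requires at least one missing cell")
    variables = table.variables
    order = _visit_order(table)
    missing = {v: table.data[v].isna().to_numpy() for v in order}
    observed_y = {v: table.data[v][~missing[v]] for v in order}
    for v in order:
        if observed_y[v].size == 0:
            raise DegenerateTargetError(f"variable {v!r} has no observed values")
        if variables[v].scale == "binary" and observed_y[v].nunique() < 2:
            raise DegenerateTargetError(f"binary variable {v!r} observed as a single class")

    # categorical values are carried as level codes inside the engine
    level_maps = {
        v.name: {lvl: float(i) for i, lvl in enumerate(v.levels)}
        for v in variables.values()
        if v.scale == "categorical"
    }

    def encode(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name, mapping in level_maps.items():
            out[name] = out[name].map(mapping)
        return out.astype(float)

    def decode(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name, mapping in level_maps.items():
            inverse = {code: lvl for lvl, code in mapping.items()}
            out[name] = out[name].map(inverse)
        return out

    base = encode(table.data)
    n = len(base)
    warn_counts: dict[str, int] = {}
    warn_sink: list[str] = []

    def flush_warnings() -> None:
        for w in warn_sink:
            warn_counts[w] = warn_counts.get(w, 0) + 1
        warn_sink.clear()

    design_cache = {
        v: _design_columns(variables, spec.predictors[v]) for v in order
    }

    def build_design(values: dict[str, np.ndarray], var: str) -> np.ndarray:
        cols = design_cache[var]
        X = np.empty((n, len(cols) + 1))
        X[:, 0] = 1.0
        for j, (name, level) in enumerate(cols, start=1):
            col = values[name]
            if level is None:
                X[:, j] = col
            else:
                X[:, j] = col == level_maps[name][level]
        return X

    tables: list[pd.DataFrame] = []
    substream_ids: list[str] = []
    for i in range(spec.m):
        sid = f"fcs/{spec.seed}/imp{i}"
        substream_ids.append(sid)
        rng = substream(spec.seed, "fcs", f"imp{i}")
        current = _start_fill(base, order, rng)
        values = {name: current[name].to_numpy(copy=True) for name in variables}
        warm: dict[str, np.ndarray] = {}
        for cycle in range(spec.cycles):
            for var in order:
                mis = missing[var]
                X = build_design(values, var)
                X_obs, X_mis = X[~mis], X[mis]
                y_obs = values[var][~mis]
                delta = float(spec.offsets.get(var, 0.0))
                method = spec.column_models[var]
                try:
                    if method == "bayes_linear":
                        imputed = impute_bayes_linear(
                            y_obs, X_obs, X_mis, delta, rng, warnings=warn_sink
                        )
                    elif method == "bayes_logistic":
                        imputed, beta, _ = impute_bayes_logistic(
                            y_obs, X_obs, X_mis, delta, rng,
                            warnings=warn_sink, beta0=warm.get(var), return_eta=True,
                        )
                        warm[var] = beta
                    elif method == "pmm":
                        imputed = impute_pmm(
                            y_obs, X_obs, X_mis, spec.pmm_donors, rng,
                            delta=delta, warnings=warn_sink,
                        )
                    else:  # polytomous
                        imputed = _impute_polytomous(
                            y_obs, X_obs, X_mis, rng, warn_sink,
                            n_levels=len(variables[var].levels),
                        )
                except (StudyTableError, DegenerateTargetError) as exc:
                    raise StudyTableError(
                        f"imputation {i}, cycle {cycle}, variable {var!r}: {exc}"
                    ) from exc
                values[var][mis] = imputed
        flush_warnings()
        completed = pd.DataFrame({name: values[name] for name in variables})
        tables.append(decode(completed))

    imputed_mask = table.data.isna()
    return ImputedStack(
        tables=tables,
        imputed_mask=imputed_mask,
        spec=spec,
        variables=list(variables.values()),
        substream_ids=substream_ids,
        warnings=warn_counts,
    )


def _impute_polytomous(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
    warn_sink: list[str],
    n_levels: int,
) -> np.ndarray:
    """One-vs-rest logistic draws normalized to a categorical draw.

    Level codes are 0..n_levels-1.  δ offsets are not supported for
    polytomous targets.
    """
    probs = np.empty((X_mis.shape[0], n_levels))
    for code in range(n_levels):
        indicator = (y_obs == code).astype(float)
        if indicator.min() == indicator.max():
            probs[:, code] = float(indicator.max())
            rng.standard_normal(X_obs.shape[1])  # keep draw counts aligned
            continue
        beta, R = _logistic_mle(X_obs, indicator)
        if np.max(np.abs(beta)) > 12.0:
            beta, R = _logistic_mle(X_obs, indicator, ridge=1.0)
            warn_sink.append("possible separation in polytomous fit: penalized fall-back")
        z = rng.standard_normal(len(beta))
        beta_draw = beta + solve_triangular(R, z, lower=False)
        probs[:, code] = expit(X_mis @ beta_draw)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(X_mis.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(float)
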