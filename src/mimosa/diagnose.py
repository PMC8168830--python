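"""Missing-data diagnostics: extent, patterns, and predictors of completeness.

Three descriptive outputs computed before any imputation is run:

1. a per-variable missingness summary with the distinct observed/missing
   patterns over the analysis-model variables;
2. a comparison of observed characteristics between complete and incomplete
   records; and
3. a logistic model for the indicator of being a complete record, which is
   the empirical evidence consumed by the strategy-selection flowchart.

A record is *complete* iff all analysis-model variables (outcome, exposure,
confounders) are observed; auxiliaries do not enter the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .studytable import StudyTable, StudyTableError

__all__ = [
    "MissingnessSummary",
    "CompletenessModel",
    "summarize_missingness",
    "compare_by_completeness",
    "predictors_of_missingness",
]


@dataclass
class MissingnessSummary:
    per_variable: pd.DataFrame  # index variable; columns n_missing, prop_missing, role
    n_records: int
    n_complete: int
    pattern_table: pd.DataFrame  # one row per distinct pattern, sorted by count
    analysis_variables: list[str]

    @property
    def complete_proportion(self) -> float:
        return self.n_complete / self.n_records

    @property
    def incomplete_proportion(self) -> float:
        return 1.0 - self.complete_proportion

    def to_frame(self) -> pd.DataFrame:
        return self.per_variable.reset_index(names="variable")


@dataclass
class CompletenessModel:
    """Logistic fit of the complete-record indicator on user-named predictors."""

    estimates: pd.DataFrame  # index predictor; coef, se, odds_ratio, ci_low, ci_high, p
    n_used: int
    n_dropped: int
    converged: bool
    separation: bool = False
    warnings: list[str] = field(default_factory=list)
    llf: float = np.nan
    llf_null: float = np.nan

    @property
    def lr_pvalue(self) -> float:
        """Likelihood-ratio test of all predictors jointly against the null."""
        if not np.isfinite(self.llf) or not np.isfinite(self.llf_null):
            return np.nan
        lr = 2.0 * (self.llf - self.llf_null)
        return float(stats.chi2.sf(max(lr, 0.0), df=len(self.estimates)))

    def coefficient(self, name: str) -> pd.Series:
        return self.estimates.loc[name]


def summarize_missingness(table: StudyTable) -> MissingnessSummary:
    """Per-variable missingness counts and the analysis-model pattern table."""
    if table.n_records == 0:
        raise StudyTableError("cannot summarize an empty table")
    mask = table.mask
    per_variable = pd.DataFrame(
        {
            "role": [v.role for v in table.variables.values()],
            "n_missing": (~mask).sum(),
            "prop_missing": (~mask).mean(),
        }
    )
    analysis = table.analysis_variables
    obs = mask[analysis]
    patterns = (
        obs.value_counts()
        .rename("count")
        .reset_index()
        .sort_values("count", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    complete = table.is_complete_record()
    return MissingnessSummary(
        per_variable=per_variable,
        n_records=table.n_records,
        n_complete=int(complete.sum()),
        pattern_table=patterns,
        analysis_variables=analysis,
    )


def compare_by_completeness(table: StudyTable) -> pd.DataFrame:
    """Observed characteristics of complete vs. incomplete records.

    Continuous variables are summarized by mean and SD, binary/categorical by
    count and percentage per level, each computed over the group's *observed*
    values only (a cell that is missing contributes to neither group's
    numerator nor denominator).  Cells with no observed values in a group are
    reported as NaN ("not estimable"), never as zero.
    """
    complete = table.is_complete_record()
    groups = {"complete": complete, "incomplete": ~complete}
    single_group = complete.all() or (~complete).all()
    rows = []
    for var in table.variables.values():
        series = table.data[var.name]
        if var.scale == "continuous":
            row = {"variable": var.name, "level": "", "statistic": "mean (SD)"}
            for label, sel in groups.items():
                observed = series[sel].dropna()
                row[f"{label}_n"] = len(observed)
                row[f"{label}_value"] = observed.mean() if len(observed) else np.nan
                row[f"{label}_spread"] = observed.std(ddof=1) if len(observed) > 1 else np.nan
            rows.append(row)
        else:
            levels = var.levels if var.scale == "categorical" else (0.0, 1.0)
            for level in levels:
                row = {"variable": var.name, "level": level, "statistic": "n (%)"}
                for label, sel in groups.items():
                    observed = series[sel].dropna()
                    n_level = int((observed == level).sum())
                    row[f"{label}_n"] = len(observed)
                    row[f"{label}_value"] = n_level
                    row[f"{label}_spread"] = (
                        100.0 * n_level / len(observed) if len(observed) else np.nan
                    )
                rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["group_sizes"] = {k: int(v.sum()) for k, v in groups.items()}
    out.attrs["single_group_warning"] = bool(single_group)
    return out


def predictors_of_missingness(
    table: StudyTable, predictors: list[str]
) -> CompletenessModel:
    """Maximum-likelihood logistic model of the complete-record indicator.

    Records with any missing predictor are dropped (count reported).  Perfect
    separation and degenerate (constant) predictors are detected and flagged
    rather than silently penalized — a diagnostic must not mask a pathology.
    """
    for name in predictors:
        if name not in table.data.columns:
            raise StudyTableError(f"unknown predictor {name!r}")
    y = table.is_complete_record().astype(float)
    X = table.data[predictors]
    keep = X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    Xk, yk = X[keep], y[keep]
    warn_list: list[str] = []
    if n_dropped:
        warn_list.append(f"dropped {n_dropped} records with missing predictor values")

    n_events = int(min(yk.sum(), (1 - yk).sum()))
    if n_events < 10:
        warn_list.append(f"fewer than 10 events ({n_events}); estimates unstable")

    degenerate = [c for c in predictors if Xk[c].nunique() <= 1]
    empty = pd.DataFrame(
        np.nan,
        index=pd.Index(predictors, name="predictor"),
        columns=["coef", "se", "odds_ratio", "ci_low", "ci_high", "p"],
    )
    if degenerate:
        warn_list.append(f"degenerate (constant) predictors: {degenerate}")
        return CompletenessModel(
            estimates=empty, n_used=int(keep.sum()), n_dropped=n_dropped,
            converged=False, warnings=warn_list,
        )
    if yk.nunique() <= 1:
        warn_list.append("completeness indicator has no variation")
        return CompletenessModel(
            estimates=empty, n_used=int(keep.sum()), n_dropped=n_dropped,
            converged=False, warnings=warn_list,
        )

    design = sm.add_constant(Xk.astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(yk, design).fit(disp=0, maxiter=100)
            converged = bool(fit.mle_retvals.get("converged", False))
        except Exception as exc:  # e.g. PerfectSeparationError
            warn_list.append(f"logistic fit failed: {exc}")
            return CompletenessModel(
                estimates=empty, n_used=int(keep.sum()), n_dropped=n_dropped,
                converged=False, separation=True, warnings=warn_list,
            )
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
    if (fit.params.drop("const").abs() > 15).any():
        separation = True
    if separation:
        warn_list.append("possible perfect separation; coefficients unreliable")
        converged = False

    ci = fit.conf_int()
    est = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "odds_ratio": np.exp(fit.params),
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    ).drop(index="const")
    est.index.name = "predictor"
    return CompletenessModel(
        estimates=est,
        n_used=int(keep.sum()),
        n_dropped=n_dropped,
        converged=converged,
        separation=separation,
        warnings=warn_list,
        llf=float(fit.llf),
        llf_null=float(fit.llnull),
    )
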