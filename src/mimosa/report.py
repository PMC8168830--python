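"""Reporting: missing-data description, methods stub, and the results table.

Renders the three diagnostic outputs, the strategy rationale, and a results
table with one row per analysis — primary multiple imputation, complete
records, and one row per sensitivity δ — with columns method / n /
coefficient (95% CI) / p / % of missing values imputed positive.  An
automatic agreement note compares the complete-records and MI estimates
against a *contextual* difference threshold expressed in outcome units
(default 2.0 score points): whether two estimates differ materially is a
substantive judgement, not a statistical test.

Every rendered number is taken from a stored result object; the JSON bundle
round-trips bit-for-bit and the markdown rendering is a pure function of the
inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnose import CompletenessModel, MissingnessSummary
from .plan import Recommendation
from .pool import PooledResult
from .sensitivity import SensitivityResult
from .studytable import StudyTableError

__all__ = ["ReportBundle", "build_results_table", "build_report", "render_markdown_table"]


def render_markdown_table(df: pd.DataFrame, float_fmt: str = "{:.3f}") -> str:
    """Minimal GitHub-style markdown table renderer."""

    def fmt(v) -> str:
        if isinstance(v, float):
            if np.isnan(v):
                return ""
            return float_fmt.format(v)
        return str(v)

    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _fmt_ci(low: float, high: float, decimals: int = 1) -> str:
    return f"({low:.{decimals}f}, {high:.{decimals}f})"


def build_results_table(
    primary: PooledResult,
    cra: PooledResult,
    sensitivity: list[SensitivityResult] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Results table: primary MI, complete records, then sensitivity rows
    in ascending δ.  The % imputed positive column is "N/A" for the
    complete-records row; each row carries the n actually used."""
    sensitivity = sorted(sensitivity or [], key=lambda r: r.delta)
    if primary.n < cra.n:
        raise StudyTableError(
            f"primary-analysis n ({primary.n}) below complete-records n ({cra.n}): "
            "inputs are not from the same table"
        )
    rows = []

    def row(label: str, res: PooledResult, prop) -> dict:
        return {
            "Method of analysis": label,
            "n": res.n,
            "Coefficient": round(res.estimate, decimals),
            "95% CI": _fmt_ci(res.ci_low, res.ci_high, decimals),
            "P": _fmt_p(res.p),
            "% imputed positive": "N/A" if prop is None else f"{100 * prop:.1f}",
        }

    primary_prop = None
    for r in sensitivity:
        if r.delta == 0.0 and r.imputed_positive_proportion is not None:
            primary_prop = r.imputed_positive_proportion
    rows.append(row("Primary analysis: multiple imputation", primary, primary_prop))
    rows.append(row("Complete records analysis", cra, None))
    for r in sensitivity:
        if r.error is not None:
            rows.append({
                "Method of analysis": f"Sensitivity analysis - delta = {r.delta:g}",
                "n": "", "Coefficient": "", "95% CI": "", "P": "",
                "% imputed positive": f"failed: {r.error}",
            })
            continue
        rows.append(
            row(
                f"Sensitivity analysis - delta = {r.delta:g}",
                r.pooled,
                r.imputed_positive_proportion,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    summary: MissingnessSummary | None = None
    comparison: pd.DataFrame | None = None
    completeness_model: CompletenessModel | None = None
    recommendation: Recommendation | None = None
    primary: PooledResult | None = None
    cra: PooledResult | None = None
    sensitivity: list[SensitivityResult] = field(default_factory=list)
    methods: dict = field(default_factory=dict)  # m, cycles, predictor sets, δ grid…
    agreement_threshold: float = 2.0  # outcome units; a contextual judgement

    # ------------------------------------------------------------- pieces
    def results_table(self) -> pd.DataFrame | None:
        if self.primary is None or self.cra is None:
            return None
        return build_results_table(self.primary, self.cra, self.sensitivity)

    def agreement(self) -> dict | None:
        if self.primary is None or self.cra is None:
            return None
        diff = abs(self.primary.estimate - self.cra.estimate)
        deltas = [
            abs(r.pooled.estimate - self.primary.estimate)
            for r in self.sensitivity
            if r.pooled is not None
        ]
        return {
            "cra_mi_difference": diff,
            "max_sensitivity_shift": max(deltas) if deltas else None,
            "threshold": self.agreement_threshold,
            "discrepancy": bool(
                diff > self.agreement_threshold
                or (deltas and max(deltas) > self.agreement_threshold)
            ),
        }

    # ------------------------------------------------------------ renders
    def to_json(self, path: str | Path | None = None) -> str:
        payload: dict = {"methods": self.methods, "agreement": self.agreement()}
        if self.summary is not None:
            payload["missingness"] = {
                "per_variable": self.summary.to_frame().to_dict(orient="records"),
                "n_records": self.summary.n_records,
                "n_complete": self.summary.n_complete,
                "patterns": self.summary.pattern_table.to_dict(orient="records"),
            }
        if self.comparison is not None:
            payload["comparison"] = self.comparison.to_dict(orient="records")
        if self.completeness_model is not None:
            cm = self.completeness_model
            payload["completeness_model"] = {
                "estimates": cm.estimates.reset_index().to_dict(orient="records"),
                "n_used": cm.n_used,
                "converged": cm.converged,
                "separation": cm.separation,
                "warnings": cm.warnings,
                "lr_pvalue": cm.lr_pvalue,
            }
        if self.recommendation is not None:
            payload["recommendation"] = json.loads(self.recommendation.to_json())
        for key, res in (("primary", self.primary), ("complete_records", self.cra)):
            if res is not None:
                payload[key] = res.to_dict()
        if self.sensitivity:
            payload["sensitivity"] = [
                {
                    "delta": r.delta,
                    "pooled": r.pooled.to_dict() if r.pooled else None,
                    "imputed_positive_proportion": r.imputed_positive_proportion,
                    "error": r.error,
                }
                for r in self.sensitivity
            ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self, path: str | Path | None = None) -> str:
        parts = ["# Missing-data analysis report", ""]

        parts.append("## Methods")
        if self.methods:
            for key, value in self.methods.items():
                parts.append(f"- **{key}**: {value}")
        else:
            parts.append("*(no methods specification supplied)*")
        parts.append("")

        parts.append("## Extent and patterns of missing data")
        if self.summary is not None:
            s = self.summary
            parts.append(
                f"{s.n_complete} of {s.n_records} records "
                f"({100 * s.complete_proportion:.1f}%) are complete on all "
                "analysis-model variables."
            )
            parts.append("")
            per_var = s.to_frame().copy()
            per_var["prop_missing"] = per_var["prop_missing"].round(4)
            parts.append(render_markdown_table(per_var, "{:.4f}"))
            parts.append("")
            pat = s.pattern_table.head(20).copy()
            parts.append("Most frequent observed/missing patterns (1 = observed):")
            parts.append(render_markdown_table(pat.astype(int)))
        else:
            parts.append("*(missingness summary not available)*")
        parts.append("")

        parts.append("## Complete vs. incomplete records")
        if self.comparison is not None:
            comp = self.comparison.copy()
            for col in comp.columns:
                if comp[col].dtype.kind == "f":
                    comp[col] = comp[col].round(2)
            parts.append(render_markdown_table(comp, "{:.2f}"))
            if self.comparison.attrs.get("single_group_warning"):
                parts.append("")
                parts.append("⚠ all records fall in a single completeness group.")
        else:
            parts.append("*(comparison not available)*")
        parts.append("")

        parts.append("## Predictors of being a complete record")
        if self.completeness_model is not None:
            cm = self.completeness_model
            est = cm.estimates.reset_index().round(4)
            parts.append(render_markdown_table(est, "{:.4f}"))
            parts.append("")
            parts.append(
                f"n = {cm.n_used}; converged = {cm.converged}; "
                f"joint LR p = {_fmt_p(cm.lr_pvalue) if np.isfinite(cm.lr_pvalue) else 'n/a'}"
            )
            for w in cm.warnings:
                parts.append(f"- ⚠ {w}")
        else:
            parts.append("*(completeness model not available)*")
        parts.append("")

        if self.recommendation is not None:
            parts.append(self.recommendation.to_markdown())
            parts.append("")

        parts.append("## Results")
        table = self.results_table()
        if table is not None:
            parts.append(render_markdown_table(table, "{:.1f}"))
            agreement = self.agreement()
            parts.append("")
            if agreement["discrepancy"]:
                parts.append(
                    "⚠ **Discrepancy**: complete-records estimate "
                    f"{self.cra.estimate:.1f} vs multiple-imputation estimate "
                    f"{self.primary.estimate:.1f} differ by more than the "
                    f"contextual threshold ({agreement['threshold']:g} outcome "
                    "units); the reasons should be discussed and the more "
                    "plausible result identified on substantive grounds."
                )
            else:
                parts.append(
                    "All analyses agree within the contextual threshold "
                    f"({agreement['threshold']:g} outcome units); missing data "
                    "appear to have limited impact on the inference."
                )
        else:
            parts.append("*(results not available)*")
        parts.append("")

        text = "\n".join(parts)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_report(
    summary: MissingnessSummary | None = None,
    comparison: pd.DataFrame | None = None,
    completeness_model: CompletenessModel | None = None,
    recommendation: Recommendation | None = None,
    primary: PooledResult | None = None,
    cra: PooledResult | None = None,
    sensitivity: list[SensitivityResult] | None = None,
    methods: dict | None = None,
    agreement_threshold: float = 2.0,
) -> ReportBundle:
    """Assemble a report bundle; absent sections render as placeholders."""
    return ReportBundle(
        summary=summary,
        comparison=comparison,
        completeness_model=completeness_model,
        recommendation=recommendation,
        primary=primary,
        cra=cra,
        sensitivity=list(sensitivity or []),
        methods=dict(methods or {}),
        agreement_threshold=agreement_threshold,
    )
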