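"""Strategy selection: a deterministic, auditable rule engine.

Encodes the three planning questions for handling missing data in an
exposure–outcome analysis as explicit rules over the diagnostics:

* **Q1** — is a complete-records analysis (CRA) likely valid?  Yes when the
  incomplete-record proportion is strictly below a threshold (default 5%)
  *and* there is no evidence that completeness depends on the outcome.
* **Q2** — is multiple imputation likely to reduce bias or improve
  precision?  Yes when Q1 fails and either auxiliary variables are declared
  or confounders are among the incomplete variables.
* **Q3** — is a sensitivity analysis required?  Yes when missingness is
  suspected to depend on the unobserved values themselves (MNAR) or
  completeness is associated with proxies of the incomplete variable.

Substantive-knowledge inputs (MNAR suspicion, outcome-relatedness of the
mechanism) are configuration flags, never inferred from data: whether data
are MNAR is untestable from the observed data alone.  Every verdict carries
the evidence that triggered it, so a stored recommendation can be replayed
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .diagnose import CompletenessModel, MissingnessSummary

__all__ = ["PlanThresholds", "Evidence", "Verdict", "Recommendation", "recommend_strategy"]

CRA = "complete_records"
MI = "multiple_imputation"


@dataclass(frozen=True)
class PlanThresholds:
    """Rule inputs: numeric thresholds plus substantive-knowledge flags."""

    max_incomplete_for_cra: float = 0.05
    missingness_association_alpha: float = 0.05
    outcome_association_flag: bool = False  # substantive: mechanism related to outcome
    mnar_suspected: bool = False
    proxy_association_flag: bool | None = None  # completeness ~ proxies of incomplete var

    def __post_init__(self) -> None:
        if not 0.0 < self.max_incomplete_for_cra < 1.0:
            raise ValueError("max_incomplete_for_cra must lie in (0, 1)")
        if not 0.0 < self.missingness_association_alpha < 1.0:
            raise ValueError("missingness_association_alpha must lie in (0, 1)")


@dataclass(frozen=True)
class Evidence:
    key: str
    value: object
    source: str


@dataclass(frozen=True)
class Verdict:
    question: str  # "Q1" | "Q2" | "Q3"
    verdict: str  # "yes" | "no" | "unknown"
    evidence: tuple[Evidence, ...]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError(f"{self.question}: every verdict must cite evidence")


@dataclass(frozen=True)
class Recommendation:
    primary_method: str  # CRA | MI
    sensitivity_required: bool
    cra_as_secondary: bool
    rationale: tuple[Verdict, ...]
    warnings: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    def to_markdown(self) -> str:
        label = {CRA: "Complete-records analysis", MI: "Multiple imputation"}
        lines = [
            "## Missing-data strategy",
            "",
            f"- **Primary method:** {label[self.primary_method]}",
            f"- **Sensitivity analysis required:** {'yes' if self.sensitivity_required else 'no'}",
            f"- **Complete-records analysis as secondary:** {'yes' if self.cra_as_secondary else 'no'}",
            "",
            "### Rationale",
        ]
        for v in self.rationale:
            lines.append(f"- **{v.question}: {v.verdict}**")
            for e in v.evidence:
                lines.append(f"  - {e.key} = {e.value} ({e.source})")
        for w in self.warnings:
            lines.append(f"- ⚠ {w}")
        return "\n".join(lines)


def _outcome_evidence(
    model: CompletenessModel | None, outcome_name: str | None, alpha: float
) -> tuple[str, list[Evidence]]:
    """Is there statistical evidence completeness depends on the outcome?

    Returns ("yes"/"no"/"unknown", evidence).  Unknown when the completeness
    model is absent, failed, or does not include the outcome as a predictor.
    """
    if model is None:
        return "unknown", [Evidence("completeness_model", "absent", "diagnose")]
    if not model.converged:
        return "unknown", [Evidence("completeness_model", "non-converged", "diagnose")]
    if outcome_name is None or outcome_name not in model.estimates.index:
        return "unknown", [
            Evidence("outcome_in_completeness_model", False, "diagnose")
        ]
    p = float(model.estimates.loc[outcome_name, "p"])
    verdict = "yes" if p < alpha else "no"
    return verdict, [
        Evidence(f"completeness_model_p[{outcome_name}]", round(p, 6), "diagnose"),
        Evidence("alpha", alpha, "thresholds"),
    ]


def recommend_strategy(
    summary: MissingnessSummary,
    completeness_model: CompletenessModel | None,
    thresholds: PlanThresholds,
    outcome_name: str | None = None,
    auxiliaries_declared: bool = False,
    incomplete_includes_confounders: bool | None = None,
) -> Recommendation:
    """Map diagnostics to a recommended strategy with a full rationale trace.

    Boundary convention: an incomplete proportion exactly equal to
    ``max_incomplete_for_cra`` counts as NOT below the threshold (strict
    inequality).
    """
    incomplete = summary.incomplete_proportion
    below = incomplete < thresholds.max_incomplete_for_cra
    outcome_assoc, outcome_ev = _outcome_evidence(
        completeness_model, outcome_name, thresholds.missingness_association_alpha
    )

    q1_evidence = [
        Evidence("incomplete_record_proportion", round(incomplete, 6), "summarize_missingness"),
        Evidence("max_incomplete_for_cra", thresholds.max_incomplete_for_cra, "thresholds"),
        Evidence("outcome_association_flag", thresholds.outcome_association_flag, "substantive"),
        *outcome_ev,
    ]
    # CRA acceptable only with low missingness AND no sign (substantive or
    # statistical) that completeness depends on the outcome.
    cra_ok = below and not thresholds.outcome_association_flag and outcome_assoc != "yes"
    if below and outcome_assoc == "unknown" and not thresholds.outcome_association_flag:
        q1_verdict = "unknown"
        cra_ok = False  # conservative: unverified outcome-dependence blocks CRA
    else:
        q1_verdict = "yes" if cra_ok else "no"
    q1 = Verdict("Q1", q1_verdict, tuple(q1_evidence))

    if incomplete_includes_confounders is None:
        incomplete_includes_confounders = bool(
            (summary.per_variable.loc[
                summary.per_variable["role"] == "confounder", "n_missing"
            ] > 0).any()
        )
    q2_evidence = [
        Evidence("auxiliaries_declared", auxiliaries_declared, "config"),
        Evidence("incomplete_includes_confounders", incomplete_includes_confounders, "summarize_missingness"),
        Evidence("q1_failed", not cra_ok, "Q1"),
    ]
    mi_beneficial = (not cra_ok) and (auxiliaries_declared or incomplete_includes_confounders)
    q2 = Verdict("Q2", "yes" if mi_beneficial else "no", tuple(q2_evidence))

    proxy = thresholds.proxy_association_flag
    q3_evidence = [
        Evidence("mnar_suspected", thresholds.mnar_suspected, "substantive"),
        Evidence(
            "proxy_association_flag",
            "unknown" if proxy is None else proxy,
            "substantive",
        ),
    ]
    sensitivity_required = bool(thresholds.mnar_suspected or proxy)
    q3 = Verdict("Q3", "yes" if sensitivity_required else "no", tuple(q3_evidence))

    warnings: list[str] = []
    if thresholds.mnar_suspected and thresholds.outcome_association_flag is False and outcome_assoc != "yes":
        warnings.append(
            "MNAR suspected in exposure/covariates without evidence that "
            "missingness relates to the outcome: a complete-records analysis "
            "may be unbiased where multiple imputation is not; interpret the "
            "MI results with caution."
        )

    primary = CRA if cra_ok else (MI if mi_beneficial else CRA)
    if not cra_ok and not mi_beneficial:
        warnings.append(
            "neither CRA validity conditions nor MI benefit conditions hold; "
            "defaulting to complete records — review auxiliaries and mechanism."
        )
    return Recommendation(
        primary_method=primary,
        sensitivity_required=sensitivity_required,
        cra_as_secondary=(primary == MI),
        rationale=(q1, q2, q3),
        warnings=tuple(warnings),
    )
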