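"""Participant-by-variable study table with roles, scales and a missingness mask.

Every stage of the pipeline consumes or produces a :class:`StudyTable`: a
rectangular table (one row per participant) whose columns carry a *role*
(outcome / exposure / confounder / auxiliary) and a *scale* (continuous /
binary / categorical).  Missing cells are stored as NaN.  Tables produced by
the synthetic-cohort generator additionally carry the pre-deletion ground
truth, so that each cell has a provenance of ``observed``, ``missing`` or
``simulated-then-deleted`` and recovery error can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

ROLES = ("outcome", "exposure", "confounder", "auxiliary")
SCALES = ("continuous", "binary", "categorical")

OBSERVED = "observed"
MISSING = "missing"
DELETED = "simulated-then-deleted"
IMPUTED = "imputed"


class StudyTableError(ValueError):
    """Invalid table structure or configuration."""


@dataclass(frozen=True)
class Variable:
    """Declaration of one column: its role in the analysis and its scale."""

    name: str
    role: str
    scale: str
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise StudyTableError(f"{self.name}: unknown role {self.role!r}")
        if self.scale not in SCALES:
            raise StudyTableError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "categorical" and not self.levels:
            raise StudyTableError(f"{self.name}: categorical variable needs a level set")


class StudyTable:
    """A participant-by-variable table plus column metadata and provenance.

    Parameters
    ----------
    data:
        One row per participant; missing cells as NaN.  Column order defines
        the declaration order used for imputation-visit tie-breaks.
    variables:
        One :class:`Variable` per column of ``data``.
    truth:
        Optional complete (pre-deletion) values with the same shape as
        ``data``; present for simulated tables so deleted cells retain their
        realized value under the ``simulated-then-deleted`` provenance flag.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        variables: Iterable[Variable],
        truth: pd.DataFrame | None = None,
        validate: bool = True,
    ) -> None:
        self.data = data.reset_index(drop=True)
        self.variables: dict[str, Variable] = {v.name: v for v in variables}
        self.truth = truth.reset_index(drop=True) if truth is not None else None
        if validate:
            self.validate()

    # ------------------------------------------------------------------ roles
    def _names_with_role(self, role: str) -> list[str]:
        return [v.name for v in self.variables.values() if v.role == role]

    @property
    def outcome(self) -> str:
        return self._names_with_role("outcome")[0]

    @property
    def exposure(self) -> str:
        return self._names_with_role("exposure")[0]

    @property
    def confounders(self) -> list[str]:
        return self._names_with_role("confounder")

    @property
    def auxiliaries(self) -> list[str]:
        return self._names_with_role("auxiliary")

    @property
    def analysis_variables(self) -> list[str]:
        """Outcome, exposure and confounders — the substantive-model columns.

        Auxiliaries are deliberately excluded: the complete-record denominator
        is defined by the analysis model.
        """
        return [
            v.name
            for v in self.variables.values()
            if v.role in ("outcome", "exposure", "confounder")
        ]

    # ------------------------------------------------------------- structure
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is observed."""
        return self.data.notna()

    def is_complete_record(self) -> pd.Series:
        """Record completeness over analysis-model variables only."""
        return self.data[self.analysis_variables].notna().all(axis=1)

    def n_missing(self) -> pd.Series:
        return self.data.isna().sum()

    def provenance(self) -> pd.DataFrame:
        """Per-cell provenance: observed / missing / simulated-then-deleted."""
        prov = pd.DataFrame(
            np.where(self.mask.to_numpy(), OBSERVED, MISSING),
            columns=self.data.columns,
        )
        if self.truth is not None:
            deleted = ~self.mask & self.truth.notna()
            prov = prov.mask(deleted, DELETED)
        return prov

    def copy(self) -> "StudyTable":
        return StudyTable(
            self.data.copy(),
            list(self.variables.values()),
            truth=None if self.truth is None else self.truth.copy(),
            validate=False,
        )

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        names = list(self.variables)
        if len(set(names)) != len(names):
            raise StudyTableError("variable names must be unique")
        if list(self.data.columns) != names:
            raise StudyTableError(
                "data columns must match declared variables in order; "
                f"got {list(self.data.columns)} vs {names}"
            )
        if len(self._names_with_role("outcome")) != 1:
            raise StudyTableError("exactly one outcome variable is required")
        if len(self._names_with_role("exposure")) != 1:
            raise StudyTableError("exactly one exposure variable is required")
        for var in self.variables.values():
            observed = self.data[var.name].dropna()
            if var.scale == "binary":
                bad = ~observed.isin([0, 1, 0.0, 1.0])
                if bad.any():
                    raise StudyTableError(
                        f"{var.name}: binary values outside {{0, 1}}: "
                        f"{sorted(observed[bad].unique())[:5]}"
                    )
            elif var.scale == "categorical":
                bad = ~observed.isin(var.levels)
                if bad.any():
                    raise StudyTableError(
                        f"{var.name}: values outside declared levels "
                        f"{var.levels}: {sorted(observed[bad].unique())[:5]}"
                    )
        if self.truth is not None and self.truth.shape != self.data.shape:
            raise StudyTableError("truth table must match data shape")

    # ------------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write data as CSV (missing cells empty) plus a YAML sidecar.

        The sidecar ``<path>.yaml`` declares roles, scales and categorical
        level sets; the optional ground-truth table is written alongside for
        test harnesses.
        """
        path = Path(path)
        self.data.to_csv(path, index=False, float_format="%.17g")
        sidecar = {
            "variables": [
                {
                    "name": v.name,
                    "role": v.role,
                    "scale": v.scale,
                    **({"levels": list(v.levels)} if v.levels else {}),
                }
                for v in self.variables.values()
            ]
        }
        Path(f"{path}.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
        if truth_path is not None and self.truth is not None:
            self.truth.to_csv(truth_path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        sidecar: str | Path | None = None,
        truth_path: str | Path | None = None,
    ) -> "StudyTable":
        path = Path(path)
        sidecar = Path(sidecar) if sidecar is not None else Path(f"{path}.yaml")
        meta = yaml.safe_load(sidecar.read_text())
        variables = [
            Variable(
                name=v["name"],
                role=v["role"],
                scale=v["scale"],
                levels=tuple(v["levels"]) if v.get("levels") else None,
            )
            for v in meta["variables"]
        ]
        numeric = [v.name for v in variables if v.scale in ("continuous", "binary")]
        data = pd.read_csv(path)
        data[numeric] = data[numeric].astype(float)
        truth = None
        if truth_path is not None:
            truth = pd.read_csv(truth_path)
            truth[numeric] = truth[numeric].astype(float)
        return cls(data, variables, truth=truth)
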