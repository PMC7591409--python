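"""Cohort data model: deficit specifications, participant-visit records, I/O.

A cohort is a long table with one row per participant-visit.  Deficit
variables are ordinary columns named by their :class:`DeficitSpec`; all
other columns follow the fixed schema in :data:`BASE_COLUMNS`.  Missing
values are empty fields in CSV and NaN/<NA> in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BASE_COLUMNS",
    "SMOKING_LEVELS",
    "DeficitSpec",
    "ParticipantVisit",
    "Cohort",
    "FrailtyResult",
    "CohortStructureError",
    "validate_cohort",
    "read_deficit_specs",
    "write_deficit_specs",
]

#: Non-deficit columns of the cohort table, in canonical order.
BASE_COLUMNS = [
    "participant_id",
    "visit_age",
    "falls_12m",
    "alive",
    "attended",
    "bmi",
    "vitd_25oh",
    "smoking",
    "prior_fracture",
]

#: Smoking is a 3-level factor; never-smoker is the reference level.
SMOKING_LEVELS = ["never", "previous", "current"]

DEFAULT_VISIT_AGES = (75, 80, 85)


class CohortStructureError(ValueError):
    """Structural defect that prevents interpreting a cohort table at all."""


@dataclass(frozen=True)
class DeficitSpec:
    """Definition of one health-deficit variable.

    Binary deficits carry a ``cutpoint``; continuous deficits carry the
    ``(v_min, v_max)`` range used for min-max rescaling, fixed after
    excluding extreme outliers per ``outlier_rule`` (a quantile pair).
    ``direction`` states which end of the scale is the unhealthy one.
    """

    name: str
    kind: Literal["binary", "continuous"]
    direction: Literal["higher_is_worse", "lower_is_worse"] = "higher_is_worse"
    cutpoint: float | None = None
    v_min: float | None = None
    v_max: float | None = None
    outlier_rule: tuple[float, float] = (0.005, 0.995)

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if self.cutpoint is None:
                raise ValueError(f"binary deficit {self.name!r} needs a cutpoint")
            if self.v_min is not None or self.v_max is not None:
                raise ValueError(f"binary deficit {self.name!r} must not set v_min/v_max")
        elif self.kind == "continuous":
            if self.cutpoint is not None:
                raise ValueError(f"continuous deficit {self.name!r} must not set a cutpoint")
            if self.v_min is None or self.v_max is None:
                raise ValueError(f"continuous deficit {self.name!r} needs v_min and v_max")
            if not self.v_min < self.v_max:
                raise ValueError(
                    f"deficit {self.name!r}: v_min ({self.v_min}) must be < v_max ({self.v_max})"
                )
        else:
            raise ValueError(f"unknown deficit kind {self.kind!r}")
        lo, hi = self.outlier_rule
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"deficit {self.name!r}: outlier_rule must satisfy 0 <= lo < hi <= 1")


@dataclass
class ParticipantVisit:
    """One participant at one visit: raw deficits, falls, status, covariates."""

    participant_id: str
    visit_age: int
    deficit_values: dict[str, float] = field(default_factory=dict)
    falls_12m: int | None = None
    alive: bool = True
    attended: bool = True
    bmi: float | None = None
    vitd_25oh: float | None = None
    smoking: str | None = None
    prior_fracture: bool | None = None


@dataclass
class FrailtyResult:
    """Per participant-visit frailty index with classification."""

    participant_id: str
    visit_age: int
    index: float
    n_items_scored: int
    frail: bool
    quintile: int | None = None


@dataclass
class Cohort:
    """Long-format cohort table plus the ordered deficit specification list.

    ``data`` holds one row per (participant_id, visit_age) with the
    :data:`BASE_COLUMNS` followed by one column per deficit.
    """

    data: pd.DataFrame
    deficit_specs: list[DeficitSpec]

    def __post_init__(self) -> None:
        missing = [c for c in BASE_COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortStructureError(f"cohort table lacks required columns: {missing}")
        dupes = self.data.duplicated(subset=["participant_id", "visit_age"])
        if dupes.any():
            key = self.data.loc[dupes.idxmax(), ["participant_id", "visit_age"]]
            raise CohortStructureError(
                f"duplicate participant-visit key ({key['participant_id']!r}, {key['visit_age']!r})"
            )

    @property
    def deficit_names(self) -> list[str]:
        return [s.name for s in self.deficit_specs]

    def __len__(self) -> int:
        return len(self.data)

    def visits(self) -> Iterator[ParticipantVisit]:
        """Iterate row-wise as :class:`ParticipantVisit` records."""
        names = self.deficit_names
        for _, row in self.data.iterrows():
            deficits = {
                n: float(row[n]) for n in names if n in row.index and pd.notna(row[n])
            }
            yield ParticipantVisit(
                participant_id=str(row["participant_id"]),
                visit_age=int(row["visit_age"]),
                deficit_values=deficits,
                falls_12m=None if pd.isna(row["falls_12m"]) else int(row["falls_12m"]),
                alive=bool(row["alive"]),
                attended=bool(row["attended"]),
                bmi=None if pd.isna(row["bmi"]) else float(row["bmi"]),
                vitd_25oh=None if pd.isna(row["vitd_25oh"]) else float(row["vitd_25oh"]),
                smoking=None if pd.isna(row["smoking"]) else str(row["smoking"]),
                prior_fracture=None
                if pd.isna(row["prior_fracture"])
                else bool(row["prior_fracture"]),
            )

    def to_csv(self, path) -> None:
        df = self.data.copy()
        for col in ("alive", "attended", "prior_fracture"):
            # booleans as 0/1 with blanks for missing, so the file diff-s cleanly
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
        df.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def read_csv(cls, path, deficit_specs: Sequence[DeficitSpec]) -> "Cohort":
        df = pd.read_csv(path, dtype={"participant_id": str, "smoking": "string"})
        df["visit_age"] = df["visit_age"].astype(int)
        df["falls_12m"] = df["falls_12m"].astype("Int64") if "falls_12m" in df else pd.NA
        for col in ("alive", "attended", "prior_fracture"):
            df[col] = df[col].map(
                lambda v: pd.NA if pd.isna(v) else bool(int(v)), na_action=None
            )
        return cls(data=df, deficit_specs=list(deficit_specs))


def validate_cohort(
    cohort: Cohort, visit_ages: Sequence[int] = DEFAULT_VISIT_AGES
) -> list[str]:
    """Check type invariants; return one finding per violated rule.

    Returns an empty list iff every record satisfies: visit age in the
    configured waves, falls_12m a non-negative integer when present,
    attendance implying vital status, and every deficit column declared
    in the spec list.  Structural defects (duplicate keys, missing
    columns) raise :class:`CohortStructureError` from the ``Cohort``
    constructor instead.  Never mutates its input.
    """
    findings: list[str] = []
    df = cohort.data
    known = set(BASE_COLUMNS) | set(cohort.deficit_names)
    for col in df.columns:
        if col not in known:
            findings.append(f"column {col!r}: not in the deficit specification list")
    bad_age = ~df["visit_age"].isin(list(visit_ages))
    for _, row in df.loc[bad_age].iterrows():
        findings.append(
            f"({row['participant_id']}, {row['visit_age']}): visit_age outside configured waves {tuple(visit_ages)}"
        )
    falls = pd.to_numeric(df["falls_12m"], errors="coerce")
    neg = falls.notna() & ((falls < 0) | (falls != falls.round()))
    for _, row in df.loc[neg].iterrows():
        findings.append(
            f"({row['participant_id']}, {row['visit_age']}): falls_12m must be a non-negative integer"
        )
    dead_attender = df["attended"].fillna(False).astype(bool) & ~df["alive"].fillna(
        True
    ).astype(bool)
    for _, row in df.loc[dead_attender].iterrows():
        findings.append(
            f"({row['participant_id']}, {row['visit_age']}): attended implies alive"
        )
    smoking_bad = df["smoking"].notna() & ~df["smoking"].isin(SMOKING_LEVELS)
    for _, row in df.loc[smoking_bad].iterrows():
        findings.append(
            f"({row['participant_id']}, {row['visit_age']}): smoking level {row['smoking']!r} not in {SMOKING_LEVELS}"
        )
    return findings


# ---------------------------------------------------------------------------
# Deficit-spec YAML round trip

def _spec_to_dict(spec: DeficitSpec) -> dict:
    d: dict = {"name": spec.name, "kind": spec.kind, "direction": spec.direction}
    if spec.kind == "binary":
        d["cutpoint"] = float(spec.cutpoint)
    else:
        d["v_min"] = float(spec.v_min)
        d["v_max"] = float(spec.v_max)
    d["outlier_rule"] = [float(spec.outlier_rule[0]), float(spec.outlier_rule[1])]
    return d


def write_deficit_specs(specs: Sequence[DeficitSpec], path) -> None:
    payload = {"deficits": [_spec_to_dict(s) for s in specs]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_deficit_specs(path) -> list[DeficitSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    specs = []
    for d in payload["deficits"]:
        rule = tuple(d.get("outlier_rule", (0.005, 0.995)))
        specs.append(
            DeficitSpec(
                name=d["name"],
                kind=d["kind"],
                direction=d.get("direction", "higher_is_worse"),
                cutpoint=d.get("cutpoint"),
                v_min=d.get("v_min"),
                v_max=d.get("v_max"),
                outlier_rule=rule,  # type: ignore[arg-type]
            )
        )
    return specs
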