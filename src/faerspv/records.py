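"""Domain objects for spontaneous safety reports.

A :class:`ReportRecord` is one version of one case as it appears in a
quarterly extract: demographics, the drugs on the report with their reporter
-assigned roles, the coded reactions (MedDRA Preferred Terms), seriousness
outcomes, therapy date ranges and indications.  Several versions of the same
``case_id`` may coexist before deduplication.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: FAERS seriousness outcome codes.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: Display grouping for outcome codes.  CA (congenital anomaly) and
#: RI (required intervention) are folded into "Other outcomes".
OUTCOME_GROUPS = {
    "DE": "Died",
    "LT": "Life threatening",
    "HO": "Hospitalized",
    "DS": "Disabled",
    "CA": "Other outcomes",
    "RI": "Other outcomes",
    "OT": "Other outcomes",
}

#: Seriousness priority used when a report carries several outcome codes and
#: a single display group must be chosen (most serious wins).
OUTCOME_PRIORITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

SEX_CODES = frozenset({"F", "M", "unknown"})

REPORTER_CODES = frozenset(
    {"physician", "pharmacist", "other_health", "consumer", "unknown"}
)


@dataclass(frozen=True)
class DrugEntry:
    """One drug row: sequence number, verbatim name, role code."""

    seq: int
    name: str
    role: str = "PS"

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown drug role code {self.role!r}")


@dataclass(frozen=True)
class TherapyEntry:
    """Therapy date range for one drug sequence on a report."""

    drug_seq: int
    start_date: _dt.date | None = None
    end_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if (
            self.start_date is not None
            and self.end_date is not None
            and self.start_date > self.end_date
        ):
            raise ValueError("therapy start_date after end_date")


@dataclass
class ReportRecord:
    """One safety report version (pre- or post-deduplication)."""

    primary_id: int
    case_id: int
    fda_date_key: int | None = None  # YYYYMMDD int, padded; dedup sort key
    fda_date: _dt.date | None = None
    event_date: _dt.date | None = None
    sex: str = "unknown"
    age_years: float | None = None
    weight_kg: float | None = None
    reporter: str = "unknown"
    country: str | None = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcomes: set[str] = field(default_factory=set)
    therapies: list[TherapyEntry] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)

    def outcome_group(self) -> str | None:
        """Most serious display group among this report's outcome codes."""
        for code in OUTCOME_PRIORITY:
            if code in self.outcomes:
                return OUTCOME_GROUPS[code]
        return None


@dataclass(frozen=True)
class SMQDefinition:
    """A Standardized MedDRA Query: a named set of Preferred Terms.

    ``scope`` records whether the PT set is the broad (sensitive) or narrow
    (specific) version of the query.  PTs are case-folded on construction.
    """

    name: str
    pts: frozenset[str]
    scope: str = "broad"

    def __post_init__(self) -> None:
        if self.scope not in {"broad", "narrow"}:
            raise ValueError("scope must be 'broad' or 'narrow'")
        if not self.pts:
            raise ValueError("SMQ PT set must be non-empty")
        folded = frozenset(p.strip().casefold() for p in self.pts)
        object.__setattr__(self, "pts", folded)
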