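"""Participant records, trait partitions, and delimited-file I/O.

A participant record is one interviewed subject: referral code, self-reported
network degree (the number of regular tobacco-and-alcohol-using contacts,
which feeds the degree-weighting step of the estimator), age, eligibility,
smoking-onset stratum, recruitment year, seed source, and a map of binary
traits (one per drug x recall window, plus derived composites).

File format: UTF-8 delimited text, comma by default (tab accepted), one
header line, columns ``pid, code, year, seed_source, age, sex,
onset_stratum, degree`` followed by ``trait:<name>:<window>`` binary columns.
Referral codes are written unquoted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .codes import ReferralCode, format_referral_code, parse_referral_code
from .errors import SchemaError, TraitValueError

#: Eligibility window for the study design (inclusive ages).
ELIGIBLE_AGE_MIN = 18
ELIGIBLE_AGE_MAX = 50

MANDATORY_COLUMNS = [
    "pid",
    "code",
    "year",
    "seed_source",
    "age",
    "sex",
    "onset_stratum",
    "degree",
]

TRAIT_PREFIX = "trait:"

ONSET_EARLY = "early"  # first tobacco use before age 18
ONSET_LATE = "late"  # first tobacco use at 18 or later


@dataclass
class ParticipantRecord:
    """One interviewed subject.

    ``traits`` maps ``"<drug>:<window>"`` (e.g. ``"ketamine:lifetime"``) to 0/1.
    ``eligible`` reflects the recruitment criteria; age outside 18-50 marks a
    record ineligible (the tobacco/alcohol/residence criteria are satisfied by
    inclusion and are not separate columns).
    """

    pid: str
    code: ReferralCode
    degree: int
    age_years: int
    sex: str = "U"
    onset_stratum: str = ONSET_LATE
    traits: dict[str, int] = field(default_factory=dict)
    year: int = 0
    seed_source: str = "community"
    eligible: bool | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.eligible is None:
            self.eligible = ELIGIBLE_AGE_MIN <= self.age_years <= ELIGIBLE_AGE_MAX

    @property
    def wave(self) -> int:
        return self.code.wave

    @property
    def is_seed(self) -> bool:
        return self.code.is_seed

    def with_traits(self, extra: dict[str, int]) -> "ParticipantRecord":
        """A copy with additional trait columns merged in."""
        merged = dict(self.traits)
        merged.update(extra)
        return replace(self, traits=merged)


@dataclass(frozen=True)
class TraitPartition:
    """A partition of participants into Markov-chain states.

    The recruitment chain's state space: every participant is assigned to
    exactly one of at least two ordered groups (e.g. ``user`` / ``non-user``
    of ketamine, or the k categories of a use-pattern variable).
    """

    trait_name: str
    groups: tuple[str, ...]
    assignment: dict[str, str]  # pid -> group label

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a trait partition needs at least 2 groups")
        bad = set(self.assignment.values()) - set(self.groups)
        if bad:
            raise ValueError(f"assignment uses labels outside groups: {sorted(bad)}")

    def group_of(self, pid: str) -> str:
        return self.assignment[pid]

    def index_of(self, group: str) -> int:
        return self.groups.index(group)

    @classmethod
    def from_binary_trait(
        cls,
        records: list[ParticipantRecord],
        trait_name: str,
        positive_label: str = "user",
        negative_label: str = "non-user",
    ) -> "TraitPartition":
        """Two-group partition from a 0/1 trait column (positive group first)."""
        assignment = {}
        for r in records:
            if trait_name not in r.traits:
                raise SchemaError(f"record {r.pid} lacks trait {trait_name!r}")
            assignment[r.pid] = positive_label if r.traits[trait_name] else negative_label
        return cls(trait_name, (positive_label, negative_label), assignment)

    @classmethod
    def from_attribute(
        cls,
        records: list[ParticipantRecord],
        attribute: str,
        groups: tuple[str, ...] | None = None,
    ) -> "TraitPartition":
        """Partition on a record attribute such as ``onset_stratum``."""
        assignment = {r.pid: str(getattr(r, attribute)) for r in records}
        if groups is None:
            groups = tuple(sorted(set(assignment.values())))
        return cls(attribute, groups, assignment)


# ---------------------------------------------------------------------------
# Delimited I/O
# ---------------------------------------------------------------------------


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records into the canonical column layout."""
    trait_names: list[str] = []
    seen = set()
    for r in records:
        for t in r.traits:
            if t not in seen:
                seen.add(t)
                trait_names.append(t)
    rows = []
    for r in records:
        row = {
            "pid": r.pid,
            "code": format_referral_code(r.code),
            "year": r.year,
            "seed_source": r.seed_source,
            "age": r.age_years,
            "sex": r.sex,
            "onset_stratum": r.onset_stratum,
            "degree": r.degree,
        }
        for t in trait_names:
            row[f"{TRAIT_PREFIX}{t.replace(':', ':')}"] = r.traits.get(t, 0)
        rows.append(row)
    columns = MANDATORY_COLUMNS + [f"{TRAIT_PREFIX}{t}" for t in trait_names]
    return pd.DataFrame(rows, columns=columns)


def write_participants(records: list[ParticipantRecord], path, sep: str = ",") -> None:
    """Write records as delimited text (lossless round trip with read)."""
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header and "," not in header else ","


def read_participants(path, sep: str | None = None) -> list[ParticipantRecord]:
    """Read a participant file; unknown ``trait:`` columns are preserved.

    Raises
    ------
    SchemaError
        A mandatory column is missing.
    TraitValueError
        A trait column holds a value other than 0 or 1.
    """
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"pid": str, "code": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"participant file {path} missing columns: {missing}")
    trait_cols = [c for c in df.columns if c.startswith(TRAIT_PREFIX)]
    for c in trait_cols:
        vals = set(pd.unique(df[c].dropna()))
        if not vals <= {0, 1}:
            raise TraitValueError(
                f"trait column {c!r} has non-binary values: {sorted(vals - {0, 1})}"
            )
    records = []
    for _, row in df.iterrows():
        traits = {c[len(TRAIT_PREFIX):]: int(row[c]) for c in trait_cols}
        records.append(
            ParticipantRecord(
                pid=str(row["pid"]),
                code=parse_referral_code(str(row["code"])),
                degree=int(row["degree"]),
                age_years=int(row["age"]),
                sex=str(row["sex"]),
                onset_stratum=str(row["onset_stratum"]),
                traits=traits,
                year=int(row["year"]),
                seed_source=str(row["seed_source"]),
            )
        )
    return records


def validate_degrees(records: list[ParticipantRecord]) -> list[ParticipantRecord]:
    """Flag records whose reported degree is inconsistent with recruiting.

    Anyone who recruited at least one other person must know at least one
    network member, so a recruiter with degree < 1 is flagged (kept in the
    data, excluded later from degree weighting) and a warning is emitted.
    """
    parents = {r.code.parent() for r in records if not r.is_seed}
    flagged = []
    for r in records:
        if r.code in parents and r.degree < 1:
            warnings.warn(
                f"participant {r.pid} recruited others but reports degree "
                f"{r.degree}; flagged and excluded from degree weighting",
                stacklevel=2,
            )
            r.flags.append("degree_inconsistent_with_recruiting")
            flagged.append(r)
    return flagged
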