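"""Domain types for indirect deterministic record linkage.

Two tabular sources are modelled: a *clinical* registry, holding at most one
observation per linkage variable per patient, and a *claims* database, holding
multi-valued event sets (every in-hospital visit, every chemotherapy session,
...). Neither source carries a shared personal identifier, so records are
matched on twelve quasi-identifying linkage variables:

====  =========================================  ==================
 id   variable                                   comparator kind
====  =========================================  ==================
 1    birth date (month/year)                    gated date
 2    sex                                        gated category
 3    consent date + facility  <-> any visit     date + facility
 4    3-year follow-up + facility <-> any visit  date + facility
 5    death date (month/year)                    single date
 6    surgery date + facility                    date + facility
 7    surgery discharge date + facility          date + facility
 8    surgery-type triple (gastrectomy,
      esophagectomy, lymph-node dissection)      binary triple
 9    chemotherapy session dates                 date set
 10   radiotherapy session dates                 date set
 11   endoscopic treatment date + facility       date + facility
 12   department of residence                    category set
====  =========================================  ==================

Dates are stored with explicit precision (:class:`PartialDate`): registries
record birth and death only to the month, and coarsened ("adjusted")
comparisons at month or year granularity are first-class protocol moves, so
precision must never be invented silently. Day imputation is an explicit,
flagged operation (:func:`impute_missing_day`).
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional


class Granularity(enum.IntEnum):
    """Calendar granularity; larger value = finer."""

    YEAR = 1
    MONTH = 2
    DAY = 3

    def is_coarser_than(self, other: "Granularity") -> bool:
        return self < other


class Source(enum.Enum):
    CLINICAL = "clinical"
    CLAIMS = "claims"


class Sex(enum.Enum):
    M = "M"
    F = "F"


class VisitKind(enum.Enum):
    """Claims-side tag on a hospital contact: outpatient visit vs inpatient stay."""

    VISIT = "V"
    STAY = "S"


@dataclass(frozen=True)
class PartialDate:
    """A Gregorian date known to year, month or day precision.

    ``day_imputed`` marks a day that was filled in by :func:`impute_missing_day`
    rather than observed; it does not participate in equality.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None
    day_imputed: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (1850 <= self.year <= 2200):
            raise ValueError(f"implausible year {self.year}")
        if self.day is not None and self.month is None:
            raise ValueError("day present without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # validates day-in-month including leap years
            datetime.date(self.year, self.month, self.day)

    @property
    def precision(self) -> Granularity:
        if self.day is not None:
            return Granularity.DAY
        if self.month is not None:
            return Granularity.MONTH
        return Granularity.YEAR

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        """Parse ISO-8601 with truncation allowed: YYYY, YYYY-MM, YYYY-MM-DD."""
        parts = text.strip().split("-")
        if not 1 <= len(parts) <= 3 or not all(p.isdigit() for p in parts):
            raise ValueError(f"unparseable partial date: {text!r}")
        return cls(*(int(p) for p in parts))

    @classmethod
    def from_date(cls, d: datetime.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def sort_key(self) -> tuple:
        """Total preorder among equal-precision dates (missing parts sort first)."""
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> datetime.date:
        if self.precision is not Granularity.DAY:
            raise ValueError("only a full date converts to datetime.date")
        return datetime.date(self.year, self.month, self.day)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.isoformat()


def impute_missing_day(d: PartialDate) -> PartialDate:
    """Impute day 01 for a month-precision date, flagged as imputed.

    Day-precision input is returned unchanged; year-only input has no month to
    anchor a day and is also returned unchanged.
    """
    if d.precision is Granularity.MONTH:
        return PartialDate(d.year, d.month, 1, day_imputed=True)
    return d


@dataclass(frozen=True)
class FacilityEvent:
    """A dated healthcare contact qualified by its establishment identifier.

    ``facility_id`` plays the role of the French FINESS code; comparison is
    exact string equality after trimming and uppercasing, applied here once.
    ``kind`` is set on claims-side visit events only (visit vs stay) and is
    ignored by equality semantics other than pool selection.
    """

    date: PartialDate
    facility_id: str
    kind: Optional[VisitKind] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        norm = self.facility_id.strip().upper()
        if not norm:
            raise ValueError("facility_id must be non-empty")
        object.__setattr__(self, "facility_id", norm)


class VariableKind(enum.Enum):
    GATE_DATE = "gate_date"            # 1
    GATE_CATEGORICAL = "gate_cat"      # 2
    DATE_FACILITY = "date_facility"    # 3, 4, 6, 7, 11
    DATE_SINGLE = "date_single"        # 5
    BINARY_TRIPLE = "binary_triple"    # 8
    DATE_SET = "date_set"              # 9, 10
    CATEGORICAL_SET = "cat_set"        # 12


@dataclass(frozen=True)
class VariableSpec:
    id: int
    name: str
    kind: VariableKind
    base_granularity: Optional[Granularity]


#: The twelve linkage variables shared by the two sources. Birth and death are
#: only ever known to the month; event dates are day-precision.
VARIABLES: Mapping[int, VariableSpec] = {
    1: VariableSpec(1, "birth_date", VariableKind.GATE_DATE, Granularity.MONTH),
    2: VariableSpec(2, "sex", VariableKind.GATE_CATEGORICAL, None),
    3: VariableSpec(3, "consent_visit", VariableKind.DATE_FACILITY, Granularity.DAY),
    4: VariableSpec(4, "followup_visit", VariableKind.DATE_FACILITY, Granularity.DAY),
    5: VariableSpec(5, "death_date", VariableKind.DATE_SINGLE, Granularity.MONTH),
    6: VariableSpec(6, "surgery", VariableKind.DATE_FACILITY, Granularity.DAY),
    7: VariableSpec(7, "surgery_discharge", VariableKind.DATE_FACILITY, Granularity.DAY),
    8: VariableSpec(8, "surgery_types", VariableKind.BINARY_TRIPLE, None),
    9: VariableSpec(9, "chemo_dates", VariableKind.DATE_SET, Granularity.DAY),
    10: VariableSpec(10, "radio_dates", VariableKind.DATE_SET, Granularity.DAY),
    11: VariableSpec(11, "endoscopy", VariableKind.DATE_FACILITY, Granularity.DAY),
    12: VariableSpec(12, "departments", VariableKind.CATEGORICAL_SET, None),
}

#: Variables whose clinical-side observation is at most a single event.
SINGLE_OBS_VARIABLES = frozenset({3, 4, 5, 6, 7, 11})


def _freeze_obs(var: int, value):
    kind = VARIABLES[var].kind
    if kind in (VariableKind.DATE_FACILITY,):
        return frozenset(value)
    if kind is VariableKind.DATE_SET:
        return frozenset(value)
    if kind is VariableKind.CATEGORICAL_SET:
        return frozenset(v.strip().upper() for v in value)
    if kind is VariableKind.DATE_SINGLE:
        if not isinstance(value, PartialDate):
            raise TypeError("death date must be a PartialDate")
        return value
    if kind is VariableKind.BINARY_TRIPLE:
        t = tuple(int(bool(v)) for v in value)
        if len(t) != 3:
            raise ValueError("surgery-type triple must have three flags")
        return t
    raise ValueError(f"variable {var} is not stored in observations")


@dataclass(frozen=True)
class SourceRecord:
    """One patient in one source.

    ``observations`` maps variable id (3-12) to that variable's observation:
    frozensets of :class:`FacilityEvent` for 3/4/6/7/11, a single
    :class:`PartialDate` for 5, frozensets of :class:`PartialDate` for 9/10, a
    0/1 triple for 8 and a frozenset of department codes for 12. Variables
    absent from the mapping are missing. On the claims side variables 3 and 4
    share one event set (any in-hospital visit), stored under both keys.
    """

    record_id: str
    source: Source
    sex: Optional[Sex] = None
    birth_date: Optional[PartialDate] = None
    observations: Mapping[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        frozen = {}
        for var, value in self.observations.items():
            if var not in VARIABLES or var in (1, 2):
                raise ValueError(f"unknown observation variable {var}")
            frozen[var] = _freeze_obs(var, value)
        if self.source is Source.CLINICAL:
            for var in SINGLE_OBS_VARIABLES:
                obs = frozen.get(var)
                if isinstance(obs, frozenset) and len(obs) > 1:
                    raise ValueError(
                        f"clinical record {self.record_id}: variable {var} "
                        f"holds {len(obs)} observations (at most one allowed)"
                    )
        object.__setattr__(self, "observations", frozen)

    # -- convenience accessors -------------------------------------------
    def events(self, var: int) -> frozenset:
        obs = self.observations.get(var)
        if obs is None:
            return frozenset()
        if isinstance(obs, frozenset):
            return obs
        return frozenset([obs])

    def has(self, var: int) -> bool:
        obs = self.observations.get(var)
        if obs is None:
            return False
        if isinstance(obs, (frozenset, tuple)):
            return len(obs) > 0
        return True

    def with_observations(self, observations: Mapping[int, object]) -> "SourceRecord":
        return replace(self, observations=dict(observations))


def recode_post2020(r: SourceRecord, cutoff_year: int = 2020) -> SourceRecord:
    """Recode observations dated after the study window end as missing.

    Facility-dated variables 4, 6, 7, 11 are dropped entirely when their event
    falls after ``cutoff_year``; chemo/radio session dates (9, 10) after the
    cutoff are filtered out of their sets. Other variables are untouched. The
    input record is not mutated; the operation is idempotent.
    """
    obs = dict(r.observations)
    changed = False
    for var in (4, 6, 7, 11):
        events = obs.get(var)
        if events:
            kept = frozenset(e for e in events if e.date.year <= cutoff_year)
            if kept != events:
                changed = True
                if kept:
                    obs[var] = kept
                else:
                    del obs[var]
    for var in (9, 10):
        dates = obs.get(var)
        if dates:
            kept = frozenset(d for d in dates if d.year <= cutoff_year)
            if kept != dates:
                changed = True
                if kept:
                    obs[var] = kept
                else:
                    del obs[var]
    if not changed:
        return r
    return r.with_observations(obs)


# ---------------------------------------------------------------------------
# Protocol step descriptions
# ---------------------------------------------------------------------------


class PoolKind(enum.Enum):
    """Which claims records are candidates: any outpatient visit, or any contact."""

    VISIT_ONLY = "visit_only"
    VISIT_OR_STAY = "visit_or_stay"


class AcceptKind(enum.Enum):
    MIN_SCORE = "min_score"
    MIN_SCORE_OR_DATES = "min_score_or_dates"
    EXACT_SCORE = "exact_score"


@dataclass(frozen=True)
class AcceptRule:
    """Acceptance rule for a scored candidate pair.

    ``max_adjusted`` caps how many coarsened ("adjusted") variable matches may
    count toward the effective score: ``None`` = unlimited, ``0`` = strict
    (only exact-granularity matches count), ``1`` = at most one adjusted
    variable, mirroring the "Score >=4 (including 1 adjusted variable)" rows.
    ``MIN_SCORE_OR_DATES`` additionally accepts an effective score of
    ``threshold - 1`` when at least ``min_dates`` distinct session dates match.
    """

    kind: AcceptKind
    threshold: int
    min_dates: int = 2
    max_adjusted: Optional[int] = None


@dataclass(frozen=True)
class StepSpec:
    """Declarative description of one linkage substep.

    ``step_variables`` lists ``(variable id, granularity)`` pairs; a
    granularity coarser than the variable's base grants a fallback coarsened
    comparison (an "adjusted" match) after the exact one fails. Categorical
    variables carry granularity ``None``. ``gate_granularity_birth`` of
    ``None`` means the step is ungated (sex and birth are then scored, not
    required).
    """

    step_id: str
    stratification: Optional[str]
    claims_pool: PoolKind
    gate_granularity_birth: Optional[Granularity]
    step_variables: tuple
    acceptance: AcceptRule

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_variables", tuple(
            (int(v), g) for v, g in self.step_variables))
        for var, gran in self.step_variables:
            base = VARIABLES[var].base_granularity
            if base is not None and gran is not None and gran > base:
                raise ValueError(
                    f"step {self.step_id}: variable {var} granularity finer than base")


# ---------------------------------------------------------------------------
# Linkage results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairScore:
    """Agreement profile of one clinical/claims candidate pair at one step."""

    clinical_id: str
    claims_id: str
    matched_variables: frozenset
    n_date_matches: int
    used_adjusted: frozenset

    @property
    def score(self) -> int:
        return len(self.matched_variables)

    def __post_init__(self) -> None:
        if not self.used_adjusted <= self.matched_variables:
            raise ValueError("used_adjusted must be a subset of matched_variables")


@dataclass(frozen=True)
class Link:
    clinical_id: str
    claims_id: str
    step_id: str
    score: int
    used_adjusted: frozenset


@dataclass(frozen=True)
class Ambiguity:
    """A record discarded at a step for having several acceptable candidates."""

    step_id: str
    record_id: str
    source: Source
    candidates: tuple


@dataclass(frozen=True)
class LinkResult:
    """Outcome of a full protocol run: one-to-one links plus failure log."""

    links: tuple
    ambiguities: tuple
    unlinked_clinical: frozenset
    step_counts: tuple  # ((step_id, n_new_links), ...)

    def __post_init__(self) -> None:
        clin = [l.clinical_id for l in self.links]
        clm = [l.claims_id for l in self.links]
        if len(set(clin)) != len(clin) or len(set(clm)) != len(clm):
            raise ValueError("links violate global one-to-one constraint")

    @property
    def n_linked(self) -> int:
        return len(self.links)

    def as_mapping(self) -> dict:
        return {l.clinical_id: l.claims_id for l in self.links}


def check_unique_ids(records: Iterable[SourceRecord]) -> None:
    seen = set()
    for r in records:
        if r.record_id in seen:
            raise ValueError(f"duplicate record id: {r.record_id}")
        seen.add(r.record_id)
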