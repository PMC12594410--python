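"""Match predicates between observations at a given date granularity.

This module is the only place equality semantics live: the engine composes
these predicates but never re-implements them. All comparators treat a missing
observation on either side as a non-match, never an error — real records are
heterogeneous and a missing value simply contributes nothing to a score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Optional, Sequence, Set

from .model import FacilityEvent, Granularity, PartialDate


class PrecisionError(ValueError):
    """Requested a granularity finer than a date's precision."""


@dataclass(frozen=True)
class MatchOutcome:
    matched: bool
    n_date_matches: int = 0
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not self.matched and (self.n_date_matches or self.adjusted):
            raise ValueError("unmatched outcome cannot carry dates or adjustment")


_NO_MATCH = MatchOutcome(False)


def coarsen(d: PartialDate, g: Granularity) -> PartialDate:
    """Truncate ``d`` to granularity ``g``; output precision equals ``g``."""
    if g > d.precision:
        raise PrecisionError(f"cannot refine {d.isoformat()} to {g.name}")
    if g is Granularity.YEAR:
        return PartialDate(d.year)
    if g is Granularity.MONTH:
        return PartialDate(d.year, d.month)
    return d


def _key(d: Optional[PartialDate], g: Granularity) -> Optional[tuple]:
    """Comparison key of ``d`` at granularity ``g``, or None if unattainable."""
    if d is None:
        return None
    if g is Granularity.YEAR:
        return (d.year,)
    if g is Granularity.MONTH:
        return (d.year, d.month) if d.month is not None else None
    return (d.year, d.month, d.day) if d.day is not None else None


def dates_match(a: Optional[PartialDate], b: Optional[PartialDate],
                g: Granularity) -> bool:
    """True iff both dates are present, coarsenable to ``g``, and equal there.

    A precision shortfall yields False rather than an error: a month-precision
    record can never day-match, which is a data fact, not a programming error.
    """
    ka = _key(a, g)
    return ka is not None and ka == _key(b, g)


def facility_event_match(obs: FacilityEvent, pool: Iterable[FacilityEvent],
                         g: Granularity,
                         base: Granularity = Granularity.DAY) -> MatchOutcome:
    """Match a single clinical event against a claims event pool.

    Both the date (at granularity ``g``) and the facility identifier must
    agree. ``adjusted`` reports whether the match was achieved at a
    granularity coarser than the variable's base.
    """
    k = _key(obs.date, g)
    if k is None:
        return _NO_MATCH
    for e in pool:
        if e.facility_id == obs.facility_id and _key(e.date, g) == k:
            return MatchOutcome(True, 1, g.is_coarser_than(base))
    return _NO_MATCH


def date_set_match(a: Iterable[PartialDate], b: Iterable[PartialDate],
                   g: Granularity,
                   base: Granularity = Granularity.DAY) -> MatchOutcome:
    """Count distinct dates of ``a`` whose coarsening at ``g`` occurs in ``b``.

    Distinctness is counted after coarsening: two sessions in the same month
    count once at MONTH granularity, so the "at least two dates" acceptance
    rule cannot be inflated by within-month repeats.
    """
    kb = {k for k in (_key(d, g) for d in b) if k is not None}
    if not kb:
        return _NO_MATCH
    ka = {k for k in (_key(d, g) for d in a) if k is not None}
    n = len(ka & kb)
    if n == 0:
        return _NO_MATCH
    return MatchOutcome(True, n, g.is_coarser_than(base))


def binary_triple_match(a: Optional[Sequence], b: Optional[Sequence]) -> bool:
    """Exact agreement of the three surgery-type flags; any missing flag fails.

    All-zero triples agree vacuously: 'no surgery of any type' is information.
    """
    if a is None or b is None:
        return False
    if len(a) != 3 or len(b) != 3 or any(v is None for v in (*a, *b)):
        return False
    return tuple(int(bool(v)) for v in a) == tuple(int(bool(v)) for v in b)


def category_set_match(a: Optional[Set[str]], b: Optional[Set[str]]) -> bool:
    """Non-empty intersection of two code sets (e.g. departments of residence)."""
    if not a or not b:
        return False
    return bool(frozenset(a) & frozenset(b))
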