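"""Step execution: gate -> stratify -> score -> accept -> resolve uniqueness.

A protocol is an ordered list of :class:`~steplink.model.StepSpec`. Each step
is run over the still-unlinked populations; accepted candidate pairs become
links only when they are unique on *both* sides of the accepted bipartite
graph — a record with several acceptable counterparts is a linkage failure at
that step (logged, and left eligible for later steps). Everything here is
deterministic: identical inputs produce identical outputs regardless of row
order, because uniqueness is resolved globally after all pairs are scored,
never greedily.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import comparators as cmp
from .model import (
    AcceptKind,
    AcceptRule,
    Ambiguity,
    Granularity,
    Link,
    LinkResult,
    PairScore,
    PoolKind,
    Sex,
    Source,
    SourceRecord,
    StepSpec,
    VariableKind,
    VARIABLES,
    VisitKind,
    check_unique_ids,
)


@dataclass(frozen=True)
class StepOutcome:
    step_id: str
    new_links: tuple          # of (Link, PairScore)
    ambiguous: tuple          # of Ambiguity
    n_candidates_examined: int


# ---------------------------------------------------------------------------
# Gate
# ---------------------------------------------------------------------------


def gate_pass(a: SourceRecord, b: SourceRecord, step: StepSpec) -> bool:
    """Sex equality plus birth-date agreement at the step's gate granularity.

    Unknown sex or birth fails every gate. Ungated steps (birth granularity
    None) always pass: sex and birth are then scored instead of required.
    """
    if step.gate_granularity_birth is None:
        return True
    if a.sex is None or b.sex is None or a.sex != b.sex:
        return False
    return cmp.dates_match(a.birth_date, b.birth_date, step.gate_granularity_birth)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _score_variable(a: SourceRecord, b: SourceRecord, var: int,
                    gran: Optional[Granularity]):
    """Return (matched, adjusted, n_dates) for one step variable.

    When the step granularity is coarser than the variable's base, the exact
    comparison is attempted first; only a coarse-only agreement is flagged
    adjusted.
    """
    spec = VARIABLES[var]
    kind = spec.kind
    if kind is VariableKind.GATE_CATEGORICAL:
        return (a.sex is not None and a.sex == b.sex), False, 0
    if kind is VariableKind.GATE_DATE:
        if cmp.dates_match(a.birth_date, b.birth_date, spec.base_granularity):
            return True, False, 0
        if gran is not None and gran < spec.base_granularity and \
                cmp.dates_match(a.birth_date, b.birth_date, gran):
            return True, True, 0
        return False, False, 0
    if kind is VariableKind.BINARY_TRIPLE:
        return cmp.binary_triple_match(a.observations.get(var),
                                       b.observations.get(var)), False, 0
    if kind is VariableKind.CATEGORICAL_SET:
        return cmp.category_set_match(a.observations.get(var),
                                      b.observations.get(var)), False, 0
    if kind is VariableKind.DATE_SINGLE:
        da = a.observations.get(var)
        db = b.observations.get(var)
        return cmp.dates_match(da, db, spec.base_granularity), False, 0
    if kind is VariableKind.DATE_FACILITY:
        events_a = a.events(var)
        if not events_a:
            return False, False, 0
        pool = b.events(var)
        base = spec.base_granularity
        for ev in events_a:  # clinical side holds at most one event
            out = cmp.facility_event_match(ev, pool, base, base)
            if out.matched:
                return True, False, 0
            if gran is not None and gran < base:
                out = cmp.facility_event_match(ev, pool, gran, base)
                if out.matched:
                    return True, True, 0
        return False, False, 0
    if kind is VariableKind.DATE_SET:
        base = spec.base_granularity
        out = cmp.date_set_match(a.events(var), b.events(var), base, base)
        if out.matched:
            return True, False, out.n_date_matches
        if gran is not None and gran < base:
            out = cmp.date_set_match(a.events(var), b.events(var), gran, base)
            if out.matched:
                return True, True, out.n_date_matches
        return False, False, 0
    raise AssertionError(f"unhandled variable kind {kind}")


def score_pair(a: SourceRecord, b: SourceRecord, step: StepSpec) -> PairScore:
    """Score one gated (or ungated) clinical/claims pair under a step.

    Each step variable contributes at most one point regardless of how many
    underlying events agree; ``n_date_matches`` aggregates distinct matched
    session dates over the step's date-set variables (chemo/radio).
    """
    matched = set()
    adjusted = set()
    n_dates = 0
    for var, gran in step.step_variables:
        ok, adj, nd = _score_variable(a, b, var, gran)
        if ok:
            matched.add(var)
            if adj:
                adjusted.add(var)
            n_dates += nd
    return PairScore(a.record_id, b.record_id, frozenset(matched),
                     n_dates, frozenset(adjusted))


def effective_score(s: PairScore, rule: AcceptRule) -> int:
    """Score after applying the rule's cap on counted adjusted matches."""
    if rule.max_adjusted is None:
        return s.score
    n_adj = len(s.used_adjusted)
    return (s.score - n_adj) + min(rule.max_adjusted, n_adj)


def accept(s: PairScore, rule: AcceptRule) -> bool:
    eff = effective_score(s, rule)
    if rule.kind is AcceptKind.MIN_SCORE:
        return eff >= rule.threshold
    if rule.kind is AcceptKind.MIN_SCORE_OR_DATES:
        return eff >= rule.threshold or (
            eff == rule.threshold - 1 and s.n_date_matches >= rule.min_dates)
    if rule.kind is AcceptKind.EXACT_SCORE:
        return s.score == rule.threshold
    raise AssertionError(f"unhandled rule {rule.kind}")


# ---------------------------------------------------------------------------
# Stratification and candidate pools
# ---------------------------------------------------------------------------


def _has_surgery_data(r: SourceRecord) -> bool:
    triple = r.observations.get(8)
    return bool(r.events(6) or r.events(7) or (triple and any(triple)))


def block_key(r: SourceRecord, step: StepSpec) -> Optional[tuple]:
    """Blocking key of a record at a step; None = excluded from the step.

    Part-1 strata are presence/absence indicators of the step's treatment
    data (always computable); only a missing sex excludes a record from the
    sex-blocked steps — where it could never pass the gate anyway. Part-2
    steps use a single block.
    """
    name = step.stratification
    if name is None:
        return ()
    if name == "surgery_death":
        return (_has_surgery_data(r), r.has(5))
    if name == "sex_chemo":
        return None if r.sex is None else (r.sex, r.has(9))
    if name == "sex_radio":
        return None if r.sex is None else (r.sex, r.has(10))
    if name == "endoscopy":
        return (r.has(11),)
    raise ValueError(f"unknown stratification {name!r}")


def in_claims_pool(r: SourceRecord, pool: PoolKind) -> bool:
    """Claims candidates must have at least one in-hospital contact.

    ``VISIT_ONLY`` restricts to patients with an outpatient visit event;
    ``VISIT_OR_STAY`` admits any hospital contact (part-2 pool expansion).
    """
    visits = r.events(3)
    if not visits:
        return False
    if pool is PoolKind.VISIT_OR_STAY:
        return True
    return any(e.kind in (None, VisitKind.VISIT) for e in visits)


def stratify(clinical_pool: Sequence[SourceRecord],
             claims_pool: Sequence[SourceRecord],
             step: StepSpec) -> List[Tuple[list, list]]:
    """Partition both pools into candidate blocks for a step.

    Records in different blocks are never compared within the step; records
    whose blocking attribute excludes them (missing sex on a sex-blocked
    step) appear in no block.
    """
    claims_f = [r for r in claims_pool if in_claims_pool(r, step.claims_pool)]
    blocks: Dict[tuple, Tuple[list, list]] = {}
    for r in clinical_pool:
        k = block_key(r, step)
        if k is not None:
            blocks.setdefault(k, ([], []))[0].append(r)
    for r in claims_f:
        k = block_key(r, step)
        if k is not None:
            blocks.setdefault(k, ([], []))[1].append(r)
    return [blocks[k] for k in sorted(blocks, key=repr)]


def _gate_key(r: SourceRecord, g: Optional[Granularity]) -> Optional[tuple]:
    if g is None:
        return ()
    if r.sex is None or r.birth_date is None:
        return None
    bk = cmp._key(r.birth_date, g)
    if bk is None:
        return None
    return (r.sex, bk)


# ---------------------------------------------------------------------------
# Step and protocol execution
# ---------------------------------------------------------------------------


def run_step(clinical_unlinked: Sequence[SourceRecord],
             claims_unlinked: Sequence[SourceRecord],
             step: StepSpec) -> StepOutcome:
    """Execute one substep and resolve one-to-one uniqueness globally.

    A pair becomes a link iff it is accepted and both its records have exactly
    one accepted candidate (degree 1 on both sides of the accepted bipartite
    graph). All other accepted pairs are logged as ambiguous and their records
    stay eligible for later steps.
    """
    g = step.gate_granularity_birth
    # Index claims candidates by (block key, gate key): both are pure equality
    # constraints, so the index prunes without changing results.
    index: Dict[tuple, list] = {}
    for r in claims_unlinked:
        if not in_claims_pool(r, step.claims_pool):
            continue
        bk = block_key(r, step)
        if bk is None:
            continue
        gk = _gate_key(r, g)
        if gk is None:
            continue
        index.setdefault((bk, gk), []).append(r)

    accepted: List[PairScore] = []
    n_examined = 0
    for a in clinical_unlinked:
        bk = block_key(a, step)
        if bk is None:
            continue
        gk = _gate_key(a, g)
        if gk is None:
            continue
        for b in index.get((bk, gk), ()):
            n_examined += 1
            s = score_pair(a, b, step)
            if accept(s, step.acceptance):
                accepted.append(s)

    return StepOutcome(step.step_id, *(_resolve_unique(accepted, step)),
                       n_candidates_examined=n_examined)


def _resolve_unique(accepted: Sequence[PairScore], step: StepSpec):
    deg_clin: Dict[str, List[str]] = {}
    deg_clm: Dict[str, List[str]] = {}
    for s in accepted:
        deg_clin.setdefault(s.clinical_id, []).append(s.claims_id)
        deg_clm.setdefault(s.claims_id, []).append(s.clinical_id)
    links = []
    for s in accepted:
        if len(deg_clin[s.clinical_id]) == 1 and len(deg_clm[s.claims_id]) == 1:
            links.append((Link(s.clinical_id, s.claims_id, step.step_id,
                               s.score, s.used_adjusted), s))
    ambiguities = []
    for rid in sorted(deg_clin):
        if len(deg_clin[rid]) > 1:
            ambiguities.append(Ambiguity(step.step_id, rid, Source.CLINICAL,
                                         tuple(sorted(deg_clin[rid]))))
    for rid in sorted(deg_clm):
        if len(deg_clm[rid]) > 1:
            ambiguities.append(Ambiguity(step.step_id, rid, Source.CLAIMS,
                                         tuple(sorted(deg_clm[rid]))))
    links.sort(key=lambda ls: ls[0].clinical_id)
    return tuple(links), tuple(ambiguities)


def run_protocol(clinical: Sequence[SourceRecord],
                 claims: Sequence[SourceRecord],
                 steps: Sequence[StepSpec]) -> Tuple[LinkResult, List[StepOutcome]]:
    """Chain substeps, removing linked records from both pools after each.

    Input records are expected to be preprocessed (post-window recoding, date
    truncations). Duplicate record ids within a source are an input error.
    """
    check_unique_ids(clinical)
    check_unique_ids(claims)
    clinical_pool = list(clinical)
    claims_pool = list(claims)
    links: List[Link] = []
    ambiguities: List[Ambiguity] = []
    step_counts = []
    outcomes = []
    for step in steps:
        outcome = run_step(clinical_pool, claims_pool, step)
        outcomes.append(outcome)
        new_links = [l for l, _ in outcome.new_links]
        links.extend(new_links)
        ambiguities.extend(outcome.ambiguous)
        step_counts.append((step.step_id, len(new_links)))
        linked_clin = {l.clinical_id for l in new_links}
        linked_clm = {l.claims_id for l in new_links}
        if linked_clin:
            clinical_pool = [r for r in clinical_pool
                             if r.record_id not in linked_clin]
            claims_pool = [r for r in claims_pool
                           if r.record_id not in linked_clm]
    result = LinkResult(tuple(links), tuple(ambiguities),
                        frozenset(r.record_id for r in clinical_pool),
                        tuple(step_counts))
    return result, outcomes
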