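"""The canonical 13-substep linkage protocol and its preprocessing.

Part 1 (substeps 1, 1.A, 1.B, 2, 3, 4) matches on a stratified population —
blocking on surgery/death data, then sex x chemotherapy, sex x radiotherapy,
then endoscopy — with sex and month/year of birth required to agree before
scoring. Part 2 (substeps 5-7) drops stratification, widens the claims pool
from "any outpatient visit" to "any hospital contact", relaxes the birth gate
to year (steps 5-6) and finally removes the gate altogether (step 7), scoring
sex and birth like any other variable with exact-score thresholds 9, 7, 6.

Gate variables (birth, sex) count toward every substep's score; this is what
makes "score >= 4" attainable at substeps whose step-specific variable list
has only three entries, and distinguishes "3 variables with at least two
matching session dates" from the plain threshold.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, List, Optional, Sequence

import yaml

from .model import (
    AcceptKind,
    AcceptRule,
    Granularity,
    PartialDate,
    PoolKind,
    Source,
    SourceRecord,
    StepSpec,
)
from .comparators import coarsen

DAY = Granularity.DAY
MONTH = Granularity.MONTH
YEAR = Granularity.YEAR

#: Claims-side observation window: event dates outside it are not usable.
WINDOW_YEARS = (2015, 2020)
#: Observations after this year are recoded missing in both sources.
CUTOFF_YEAR = 2020


def canonical_protocol() -> List[StepSpec]:
    """The 13 substeps of the registry/claims linkage, in execution order."""
    min4 = AcceptRule(AcceptKind.MIN_SCORE, 4)
    min4_or_dates = AcceptRule(AcceptKind.MIN_SCORE_OR_DATES, 4, min_dates=2)
    min4_strict = AcceptRule(AcceptKind.MIN_SCORE, 4, max_adjusted=0)
    min4_one_adj = AcceptRule(AcceptKind.MIN_SCORE, 4, max_adjusted=1)

    part1_base = ((1, MONTH), (2, None))
    step1_vars = part1_base + ((3, DAY), (4, DAY), (5, MONTH), (6, DAY), (7, DAY))
    step1a_vars = part1_base + ((3, DAY), (4, DAY), (5, MONTH), (6, MONTH), (7, DAY))
    step1b_vars = part1_base + ((3, DAY), (4, DAY), (5, MONTH), (6, DAY), (7, MONTH))

    # Part 2: birth may fall back to year-only agreement (adjusted).
    part2_exact = ((1, YEAR), (2, None), (3, DAY), (4, DAY), (5, MONTH),
                   (6, DAY), (7, DAY), (9, DAY), (10, DAY), (11, DAY))
    part2_adjusted = ((1, YEAR), (2, None), (3, MONTH), (4, MONTH), (5, MONTH),
                      (6, MONTH), (7, MONTH), (9, DAY), (10, DAY), (11, DAY))

    return [
        StepSpec("1", "surgery_death", PoolKind.VISIT_ONLY, MONTH,
                 step1_vars, min4),
        StepSpec("1.A", "surgery_death", PoolKind.VISIT_ONLY, MONTH,
                 step1a_vars, min4),
        StepSpec("1.B", "surgery_death", PoolKind.VISIT_ONLY, MONTH,
                 step1b_vars, min4),
        StepSpec("2", "sex_chemo", PoolKind.VISIT_ONLY, MONTH,
                 part1_base + ((3, DAY), (4, DAY), (9, DAY)), min4_or_dates),
        StepSpec("3", "sex_radio", PoolKind.VISIT_ONLY, MONTH,
                 part1_base + ((3, DAY), (4, DAY), (10, DAY)), min4_or_dates),
        StepSpec("4", "endoscopy", PoolKind.VISIT_ONLY, MONTH,
                 part1_base + ((3, DAY), (4, DAY), (11, DAY)), min4),
        StepSpec("5-strict", None, PoolKind.VISIT_OR_STAY, YEAR,
                 part2_exact, min4_strict),
        StepSpec("5-adjusted", None, PoolKind.VISIT_OR_STAY, YEAR,
                 part2_exact, min4_one_adj),
        StepSpec("6-strict", None, PoolKind.VISIT_OR_STAY, YEAR,
                 part2_adjusted, min4_strict),
        StepSpec("6-adjusted", None, PoolKind.VISIT_OR_STAY, YEAR,
                 part2_adjusted, min4_one_adj),
        StepSpec("7-s9", None, PoolKind.VISIT_OR_STAY, None,
                 part2_adjusted, AcceptRule(AcceptKind.EXACT_SCORE, 9)),
        StepSpec("7-s7", None, PoolKind.VISIT_OR_STAY, None,
                 part2_adjusted, AcceptRule(AcceptKind.EXACT_SCORE, 7)),
        StepSpec("7-s6", None, PoolKind.VISIT_OR_STAY, None,
                 part2_adjusted, AcceptRule(AcceptKind.EXACT_SCORE, 6)),
    ]


#: Substeps belonging to part 1 (stratified matching).
PART1_STEP_IDS = ("1", "1.A", "1.B", "2", "3", "4")


# ---------------------------------------------------------------------------
# Preprocessing (window restrictions and truncations)
# ---------------------------------------------------------------------------


def preprocess(records: Iterable[SourceRecord],
               cutoff_year: int = CUTOFF_YEAR,
               window: tuple = WINDOW_YEARS) -> List[SourceRecord]:
    """Apply the data-preparation rules both sources require before linking.

    * observations after ``cutoff_year`` are recoded missing (variables 4, 6,
      7, 11) or filtered (9, 10);
    * birth and death dates are truncated to month/year;
    * claims-side treatment variables (6, 7, 9, 10, 11) are restricted to the
      observation window.
    """
    from .model import recode_post2020  # local import avoids cycle at typing time

    out = []
    for r in records:
        r = recode_post2020(r, cutoff_year)
        obs = dict(r.observations)
        changed = False
        birth = r.birth_date
        if birth is not None and birth.precision is DAY:
            birth = coarsen(birth, MONTH)
            changed = True
        death = obs.get(5)
        if death is not None and death.precision is DAY:
            obs[5] = coarsen(death, MONTH)
            changed = True
        if r.source is Source.CLAIMS:
            lo, hi = window
            for var in (6, 7, 11):
                events = obs.get(var)
                if events:
                    kept = frozenset(e for e in events if lo <= e.date.year <= hi)
                    if kept != events:
                        changed = True
                        obs[var] = kept
                        if not kept:
                            del obs[var]
            for var in (9, 10):
                dates = obs.get(var)
                if dates:
                    kept = frozenset(d for d in dates if lo <= d.year <= hi)
                    if kept != dates:
                        changed = True
                        obs[var] = kept
                        if not kept:
                            del obs[var]
        if changed or birth is not r.birth_date:
            import dataclasses
            r = dataclasses.replace(r, birth_date=birth, observations=obs)
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------


def _step_to_dict(s: StepSpec) -> dict:
    return {
        "step_id": s.step_id,
        "stratification": s.stratification,
        "claims_pool": s.claims_pool.value,
        "gate_granularity_birth": (s.gate_granularity_birth.name
                                   if s.gate_granularity_birth else None),
        "variables": [{"id": v, "granularity": g.name if g else None}
                      for v, g in s.step_variables],
        "acceptance": {
            "kind": s.acceptance.kind.value,
            "threshold": s.acceptance.threshold,
            "min_dates": s.acceptance.min_dates,
            "max_adjusted": s.acceptance.max_adjusted,
        },
    }


def _step_from_dict(d: dict) -> StepSpec:
    acc = d["acceptance"]
    return StepSpec(
        step_id=str(d["step_id"]),
        stratification=d.get("stratification"),
        claims_pool=PoolKind(d["claims_pool"]),
        gate_granularity_birth=(Granularity[d["gate_granularity_birth"]]
                                if d.get("gate_granularity_birth") else None),
        step_variables=tuple((v["id"],
                              Granularity[v["granularity"]] if v["granularity"] else None)
                             for v in d["variables"]),
        acceptance=AcceptRule(AcceptKind(acc["kind"]), acc["threshold"],
                              acc.get("min_dates", 2), acc.get("max_adjusted")),
    )


def protocol_to_yaml(steps: Sequence[StepSpec]) -> str:
    return yaml.safe_dump({"steps": [_step_to_dict(s) for s in steps]},
                          sort_keys=False)


def protocol_from_yaml(text: str) -> List[StepSpec]:
    data = yaml.safe_load(text)
    return [_step_from_dict(d) for d in data["steps"]]


def load_protocol(path: Optional[str] = None) -> List[StepSpec]:
    """Load a protocol config; default is the packaged canonical protocol."""
    if path is None:
        ref = importlib.resources.files("steplink") / "data" / "canonical_protocol.yaml"
        return protocol_from_yaml(ref.read_text())
    with open(path) as fh:
        return protocol_from_yaml(fh.read())
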