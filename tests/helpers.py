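"""Shared builders and a brute-force protocol oracle for the tests.

The oracle enumerates every clinical x claims pair (no candidate indexing)
and applies the gate / stratum / score / accept / uniqueness rules directly,
so the engine's blocking and gate-index machinery can be checked against
exhaustive enumeration.
"""

from steplink.engine import (
    accept,
    block_key,
    gate_pass,
    in_claims_pool,
    score_pair,
)
from steplink.model import (
    FacilityEvent,
    PartialDate,
    Sex,
    Source,
    SourceRecord,
    VisitKind,
)


def pdate(s):
    return PartialDate.parse(s)


def fev(s, fac="F001", kind=None):
    return FacilityEvent(pdate(s), fac, kind)


def _event(val, default_kind=None):
    if isinstance(val, FacilityEvent):
        return val
    if isinstance(val, tuple):
        return fev(val[0], val[1], default_kind)
    return fev(val, kind=default_kind)


def make_clinical(rid, sex="M", birth="1958-04", consent=None, followup=None,
                  death=None, surgery=None, discharge=None, chemo=(),
                  radio=(), endoscopy=None, triple=None, departments=()):
    obs = {}
    for var, val in ((3, consent), (4, followup), (6, surgery),
                     (7, discharge), (11, endoscopy)):
        if val is not None:
            obs[var] = {_event(val)}
    if death is not None:
        obs[5] = pdate(death)
    if chemo:
        obs[9] = {pdate(d) for d in chemo}
    if radio:
        obs[10] = {pdate(d) for d in radio}
    if triple is not None:
        obs[8] = triple
    if departments:
        obs[12] = set(departments)
    return SourceRecord(rid, Source.CLINICAL,
                        Sex(sex) if sex else None,
                        pdate(birth) if birth else None, obs)


def make_claims(rid, sex="M", birth="1958-04", visits=(), death=None,
                surgery=None, discharge=None, chemo=(), radio=(),
                endoscopy=None, triple=None, departments=()):
    obs = {}
    vset = {_event(v, VisitKind.VISIT) for v in visits}
    if vset:
        obs[3] = vset
        obs[4] = vset
    for var, val in ((6, surgery), (7, discharge), (11, endoscopy)):
        if val is not None:
            obs[var] = {_event(val)}
    if death is not None:
        obs[5] = pdate(death)
    if chemo:
        obs[9] = {pdate(d) for d in chemo}
    if radio:
        obs[10] = {pdate(d) for d in radio}
    if triple is not None:
        obs[8] = triple
    if departments:
        obs[12] = set(departments)
    return SourceRecord(rid, Source.CLAIMS,
                        Sex(sex) if sex else None,
                        pdate(birth) if birth else None, obs)


def oracle_protocol(clinical, claims, steps):
    """Exhaustive all-pairs reference run; returns {(clinical, claims, step)}."""
    clin = list(clinical)
    clm = list(claims)
    links = set()
    for step in steps:
        accepted = []
        for a in clin:
            ka = block_key(a, step)
            if ka is None:
                continue
            for b in clm:
                if not in_claims_pool(b, step.claims_pool):
                    continue
                if block_key(b, step) != ka:
                    continue
                if not gate_pass(a, b, step):
                    continue
                s = score_pair(a, b, step)
                if accept(s, step.acceptance):
                    accepted.append(s)
        deg_c, deg_m = {}, {}
        for s in accepted:
            deg_c[s.clinical_id] = deg_c.get(s.clinical_id, 0) + 1
            deg_m[s.claims_id] = deg_m.get(s.claims_id, 0) + 1
        new = [s for s in accepted
               if deg_c[s.clinical_id] == 1 and deg_m[s.claims_id] == 1]
        links |= {(s.clinical_id, s.claims_id, step.step_id) for s in new}
        gone_c = {s.clinical_id for s in new}
        gone_m = {s.claims_id for s in new}
        clin = [r for r in clin if r.record_id not in gone_c]
        clm = [r for r in clm if r.record_id not in gone_m]
    return links
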