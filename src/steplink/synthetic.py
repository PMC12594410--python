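"""Synthetic dual-registry generator with linked ground truth.

Emulates two overlapping patient populations with the variable structure the
linkage relies on: a clinical registry (one consent visit, one 3-year
follow-up, one surgery episode, chemo/radio treatment lines, one optional
endoscopy, month-precision birth and death) and a claims database (every
in-hospital visit or stay, every treatment session, 2015-2020 window). A
configurable degradation model injects the error sources the method must
survive — missing variables, shifted dates, swapped facility codes —
into the registry side, where entry errors typically arise.

All draws come from a single seeded :class:`numpy.random.Generator` in a
fixed order, so a config + seed reproduces the same pair byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import (
    FacilityEvent,
    PartialDate,
    Sex,
    Source,
    SourceRecord,
    VisitKind,
)

_WINDOW_START = datetime.date(2015, 1, 1)
_INDEX_END = datetime.date(2019, 12, 31)          # selection period end
_WINDOW_END = datetime.date(2020, 12, 31)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated registry/claims pair.

    Cohort structure mirrors the linkage study: 1617 registry patients, of
    whom a fraction also appear in the claims extract, alongside claims-only
    patients from the wider national cohort. Treatment prevalences follow the
    registry population (surgery 73%, chemotherapy 86%, radiotherapy 19%,
    endoscopic treatment 2%); male fraction 76%; mean age at diagnosis 64
    (SD 12.5) years. Error rates default to a few percent of isolated entry
    errors plus 10% per-variable missingness on the registry side.
    """

    n_clinical: int = 1617
    n_claims_extra: int = 3000
    overlap_fraction: float = 0.9
    p_male: float = 0.764
    p_surgery: float = 0.73
    p_chemo: float = 0.86
    p_radio: float = 0.19
    p_endoscopy: float = 0.02
    p_death: float = 0.35
    chemo_sessions_mean: float = 8.0
    radio_sessions_mean: float = 5.0
    extra_visits_mean: float = 3.0
    n_facilities: int = 42
    n_departments: int = 95
    p_missing: float = 0.10
    p_date_error: float = 0.05
    date_error_max_days: int = 7
    p_facility_error: float = 0.02
    p_birth_day_missing: float = 1.0
    p_post_window_spill: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_fraction", "p_male", "p_surgery", "p_chemo",
                     "p_radio", "p_endoscopy", "p_death", "p_missing",
                     "p_date_error", "p_facility_error", "p_birth_day_missing",
                     "p_post_window_spill"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


# ---------------------------------------------------------------------------
# Care pathways
# ---------------------------------------------------------------------------


def _rand_date(rng, start: datetime.date, end: datetime.date) -> datetime.date:
    span = (end - start).days
    return start + datetime.timedelta(days=int(rng.integers(0, span + 1)))


def _facility(i: int) -> str:
    return f"F{i:03d}"


def _pathway(rng: np.random.Generator, cfg: SyntheticConfig) -> dict:
    """Draw one patient's care pathway (the shared ground truth)."""
    index = _rand_date(rng, _WINDOW_START, _INDEX_END)
    age = float(np.clip(rng.normal(63.8, 12.5), 25, 94))
    birth_year = index.year - int(round(age))
    birth = datetime.date(birth_year, int(rng.integers(1, 13)),
                          int(rng.integers(1, 29)))
    home = _facility(int(rng.integers(cfg.n_facilities)))
    p = {
        "sex": Sex.M if rng.random() < cfg.p_male else Sex.F,
        "birth": birth,
        "department": f"D{int(rng.integers(1, cfg.n_departments + 1)):02d}",
        "consent": (index + datetime.timedelta(days=int(rng.integers(0, 31))), home),
    }
    fu = p["consent"][0] + datetime.timedelta(days=int(365 * 3 + rng.integers(-30, 31)))
    p["followup"] = (fu, home)
    if rng.random() < cfg.p_surgery:
        sdate = index + datetime.timedelta(days=int(rng.integers(20, 151)))
        p["surgery"] = (sdate, home)
        p["discharge"] = (sdate + datetime.timedelta(days=int(rng.integers(3, 16))), home)
        p["surgery_types"] = (int(rng.random() < 0.72),
                              int(rng.random() < 0.41),
                              int(rng.random() < 0.94))
    else:
        p["surgery_types"] = (0, 0, 0)
    if rng.random() < cfg.p_chemo:
        n = 1 + int(rng.poisson(cfg.chemo_sessions_mean))
        offsets = sorted(set(int(o) for o in rng.integers(0, 401, size=n)))
        p["chemo"] = [index + datetime.timedelta(days=o) for o in offsets]
    if rng.random() < cfg.p_radio:
        n = 1 + int(rng.poisson(cfg.radio_sessions_mean))
        offsets = sorted(set(int(o) for o in rng.integers(0, 301, size=n)))
        p["radio"] = [index + datetime.timedelta(days=o) for o in offsets]
    if rng.random() < cfg.p_endoscopy:
        p["endoscopy"] = (index + datetime.timedelta(days=int(rng.integers(0, 61))), home)
    if rng.random() < cfg.p_death:
        death = index + datetime.timedelta(days=int(rng.integers(100, 2001)))
        if death <= _WINDOW_END or rng.random() < cfg.p_post_window_spill:
            p["death"] = death
    return p


def _pd(d: datetime.date) -> PartialDate:
    return PartialDate.from_date(d)


def _clinical_record(rid: str, p: dict, birth: PartialDate) -> SourceRecord:
    obs: Dict[int, object] = {}
    for var, key in ((3, "consent"), (4, "followup"), (6, "surgery"),
                     (7, "discharge"), (11, "endoscopy")):
        if key in p:
            d, fac = p[key]
            obs[var] = {FacilityEvent(_pd(d), fac)}
    if "death" in p:
        obs[5] = _pd(p["death"])
    obs[8] = p["surgery_types"]
    for var, key in ((9, "chemo"), (10, "radio")):
        if key in p:
            dates = p[key]
            # registry stores start/end dates of each treatment line
            obs[var] = {_pd(dates[0]), _pd(dates[-1])}
    obs[12] = {p["department"]}
    return SourceRecord(rid, Source.CLINICAL, p["sex"], birth, obs)


def _claims_record(rng: np.random.Generator, cfg: SyntheticConfig,
                   rid: str, p: dict, birth: PartialDate) -> SourceRecord:
    visits = {FacilityEvent(_pd(p["consent"][0]), p["consent"][1], VisitKind.VISIT)}
    fu, fac = p["followup"]
    if fu <= _WINDOW_END:
        visits.add(FacilityEvent(_pd(fu), fac, VisitKind.VISIT))
    if "surgery" in p:
        visits.add(FacilityEvent(_pd(p["surgery"][0]), p["surgery"][1],
                                 VisitKind.STAY))
    for _ in range(int(rng.poisson(cfg.extra_visits_mean))):
        d = _rand_date(rng, _WINDOW_START, _WINDOW_END)
        f = _facility(int(rng.integers(cfg.n_facilities)))
        kind = VisitKind.VISIT if rng.random() < 0.7 else VisitKind.STAY
        visits.add(FacilityEvent(_pd(d), f, kind))
    obs: Dict[int, object] = {3: visits, 4: visits}
    if "surgery" in p:
        obs[6] = {FacilityEvent(_pd(p["surgery"][0]), p["surgery"][1])}
        obs[7] = {FacilityEvent(_pd(p["discharge"][0]), p["discharge"][1])}
    obs[8] = p["surgery_types"]
    if "chemo" in p:
        obs[9] = {_pd(d) for d in p["chemo"]}
    if "radio" in p:
        obs[10] = {_pd(d) for d in p["radio"]}
    if "endoscopy" in p:
        obs[11] = {FacilityEvent(_pd(p["endoscopy"][0]), p["endoscopy"][1])}
    if "death" in p:
        obs[5] = PartialDate(p["death"].year, p["death"].month)
    obs[12] = {p["department"]}
    return SourceRecord(rid, Source.CLAIMS, p["sex"], birth, obs)


# ---------------------------------------------------------------------------
# Degradation (entry errors and missingness)
# ---------------------------------------------------------------------------


def _shift_pd(d: PartialDate, days: int) -> PartialDate:
    return PartialDate.from_date(d.to_date() + datetime.timedelta(days=days))


def degrade(record: SourceRecord, cfg: SyntheticConfig,
            rng: np.random.Generator) -> SourceRecord:
    """Inject per-variable missingness, date shifts and facility swaps.

    Date shifts are +/-1..``date_error_max_days`` days and may cross a month
    boundary, which is exactly what the coarsened ("adjusted") comparison
    steps exist to absorb. With all rates zero this is the identity.
    """
    obs = dict(record.observations)
    for var in (3, 4, 6, 7, 11):
        events = obs.get(var)
        if not events:
            continue
        if rng.random() < cfg.p_missing:
            del obs[var]
            continue
        new = set()
        for e in events:
            date, fac = e.date, e.facility_id
            if e.date.precision.name == "DAY" and rng.random() < cfg.p_date_error:
                mag = int(rng.integers(1, cfg.date_error_max_days + 1))
                date = _shift_pd(date, mag if rng.random() < 0.5 else -mag)
            if rng.random() < cfg.p_facility_error:
                fac = _facility(int(rng.integers(cfg.n_facilities)))
            new.add(FacilityEvent(date, fac, e.kind))
        obs[var] = frozenset(new)
    for var in (9, 10):
        dates = obs.get(var)
        if not dates:
            continue
        if rng.random() < cfg.p_missing:
            del obs[var]
            continue
        new_dates = set()
        for d in dates:
            if rng.random() < cfg.p_date_error:
                mag = int(rng.integers(1, cfg.date_error_max_days + 1))
                d = _shift_pd(d, mag if rng.random() < 0.5 else -mag)
            new_dates.add(d)
        obs[var] = frozenset(new_dates)
    death = obs.get(5)
    if death is not None:
        if rng.random() < cfg.p_missing:
            del obs[5]
        elif death.precision.name == "DAY" and rng.random() < cfg.p_date_error:
            mag = int(rng.integers(1, cfg.date_error_max_days + 1))
            obs[5] = _shift_pd(death, mag if rng.random() < 0.5 else -mag)
    if obs.get(8) is not None and rng.random() < cfg.p_missing:
        del obs[8]
    birth = record.birth_date
    if birth is not None and rng.random() < cfg.p_date_error:
        # entry error in the birth month; may cross a year boundary, which
        # only the year-granularity gate relaxation (steps 5-6) can absorb
        m = birth.month + (1 if rng.random() < 0.5 else -1)
        y = birth.year + (1 if m > 12 else -1 if m < 1 else 0)
        m = 1 if m > 12 else 12 if m < 1 else m
        birth = PartialDate(y, m)
    if birth is not None and birth.day is not None and \
            rng.random() < cfg.p_birth_day_missing:
        birth = PartialDate(birth.year, birth.month)
    return dataclasses.replace(record, birth_date=birth, observations=obs)


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------


def generate_pair(cfg: SyntheticConfig
                  ) -> Tuple[List[SourceRecord], List[SourceRecord], Dict[str, str]]:
    """Generate (clinical records, claims records, truth map).

    Overlapping patients share one pathway rendered twice (registry view
    degraded at the configured error rates, claims view faithful); claims-only
    patients get independent pathways. The truth map is an injective
    clinical_id -> claims_id mapping over the overlap.
    """
    rng = np.random.default_rng(cfg.seed)
    n_overlap = int(round(cfg.overlap_fraction * cfg.n_clinical))
    clinical: List[SourceRecord] = []
    claims: List[SourceRecord] = []
    truth: Dict[str, str] = {}
    for i in range(cfg.n_clinical):
        cid = f"C{i + 1:05d}"
        p = _pathway(rng, cfg)
        birth_full = _pd(p["birth"])
        birth_clin = (PartialDate(birth_full.year, birth_full.month)
                      if rng.random() < cfg.p_birth_day_missing else birth_full)
        rec = degrade(_clinical_record(cid, p, birth_clin), cfg, rng)
        clinical.append(rec)
        if i < n_overlap:
            sid = f"S{i + 1:05d}"
            birth_clm = (PartialDate(birth_full.year, birth_full.month)
                         if rng.random() < cfg.p_birth_day_missing else birth_full)
            claims.append(_claims_record(rng, cfg, sid, p, birth_clm))
            truth[cid] = sid
    for j in range(cfg.n_claims_extra):
        sid = f"S{cfg.n_clinical + j + 1:05d}"
        p = _pathway(rng, cfg)
        birth_full = _pd(p["birth"])
        birth_clm = (PartialDate(birth_full.year, birth_full.month)
                     if rng.random() < cfg.p_birth_day_missing else birth_full)
        claims.append(_claims_record(rng, cfg, sid, p, birth_clm))
    # claims extract order is arbitrary in reality; shuffle deterministically
    order = rng.permutation(len(claims))
    claims = [claims[int(k)] for k in order]
    return clinical, claims, truth
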