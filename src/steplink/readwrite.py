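"""CSV readers/writers for the two source dialects and the result tables.

One row per patient. Multi-valued variables are semicolon-delimited
``YYYY-MM-DD@FACILITY`` entries (the facility part is absent for chemo/radio
session dates); claims visit events carry a trailing ``@V``/``@S`` kind tag.
Dates are ISO-8601 with truncation allowed (``1958-04``, ``1958``); missing =
empty field. The clinical schema has ``consent`` and ``followup`` columns;
the claims schema has a single ``visits`` column, because both registry
variables compare against the same set of hospital contacts.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

from .model import (
    FacilityEvent,
    Link,
    LinkResult,
    PartialDate,
    Sex,
    Source,
    SourceRecord,
    VisitKind,
)

log = logging.getLogger("steplink")

CLINICAL_COLUMNS = ["record_id", "sex", "birth_date", "consent", "followup",
                    "death", "surgery", "discharge", "surgery_types",
                    "chemo_dates", "radio_dates", "endoscopy", "departments"]
CLAIMS_COLUMNS = ["record_id", "sex", "birth_date", "visits", "death",
                  "surgery", "discharge", "surgery_types", "chemo_dates",
                  "radio_dates", "endoscopy", "departments"]

_EVENT_VARS = {"consent": 3, "followup": 4, "surgery": 6, "discharge": 7,
               "endoscopy": 11}


def _fmt_event(e: FacilityEvent, with_kind: bool = False) -> str:
    s = f"{e.date.isoformat()}@{e.facility_id}"
    if with_kind and e.kind is not None:
        s += f"@{e.kind.value}"
    return s


def _parse_event(text: str) -> FacilityEvent:
    parts = text.strip().split("@")
    if len(parts) == 2:
        return FacilityEvent(PartialDate.parse(parts[0]), parts[1])
    if len(parts) == 3:
        return FacilityEvent(PartialDate.parse(parts[0]), parts[1],
                             VisitKind(parts[2]))
    raise ValueError(f"malformed facility event: {text!r}")


def _split(field: str) -> List[str]:
    return [p for p in (field or "").split(";") if p.strip()]


def record_to_row(r: SourceRecord) -> Dict[str, str]:
    row = {
        "record_id": r.record_id,
        "sex": r.sex.value if r.sex else "",
        "birth_date": r.birth_date.isoformat() if r.birth_date else "",
        "death": r.observations[5].isoformat() if 5 in r.observations else "",
        "surgery_types": ("|".join(str(v) for v in r.observations[8])
                          if 8 in r.observations else ""),
        "chemo_dates": ";".join(sorted(d.isoformat() for d in r.events(9))),
        "radio_dates": ";".join(sorted(d.isoformat() for d in r.events(10))),
        "departments": ";".join(sorted(r.events(12))),
    }
    if r.source is Source.CLINICAL:
        for col, var in _EVENT_VARS.items():
            evs = r.events(var)
            row[col] = _fmt_event(next(iter(evs))) if evs else ""
    else:
        row["visits"] = ";".join(sorted(
            _fmt_event(e, with_kind=True) for e in r.events(3)))
        for col in ("surgery", "discharge", "endoscopy"):
            evs = r.events(_EVENT_VARS[col])
            row[col] = ";".join(sorted(_fmt_event(e) for e in evs))
    return row


def _row_to_record(row: Mapping[str, str], kind: Source,
                   rownum: int) -> SourceRecord:
    def optional(parse, field_name):
        raw = (row.get(field_name) or "").strip()
        if not raw:
            return None
        try:
            return parse(raw)
        except ValueError as exc:
            warnings.warn(f"row {rownum}: malformed {field_name} ({exc}); "
                          "set missing", stacklevel=3)
            return None

    rid = (row.get("record_id") or "").strip()
    if not rid:
        raise ValueError(f"row {rownum}: missing record_id")
    sex_raw = (row.get("sex") or "").strip().upper()
    sex = Sex(sex_raw) if sex_raw in ("M", "F") else None
    birth = optional(PartialDate.parse, "birth_date")

    obs: Dict[int, object] = {}
    if kind is Source.CLINICAL:
        for col, var in _EVENT_VARS.items():
            ev = optional(_parse_event, col)
            if ev is not None:
                obs[var] = {ev}
    else:
        visits = set()
        for part in _split(row.get("visits", "")):
            try:
                visits.add(_parse_event(part))
            except ValueError as exc:
                warnings.warn(f"row {rownum}: malformed visit ({exc}); dropped",
                              stacklevel=3)
        if visits:
            obs[3] = visits
            obs[4] = visits
        for col in ("surgery", "discharge", "endoscopy"):
            events = set()
            for part in _split(row.get(col, "")):
                try:
                    events.add(_parse_event(part))
                except ValueError as exc:
                    warnings.warn(f"row {rownum}: malformed {col} ({exc}); "
                                  "dropped", stacklevel=3)
            if events:
                obs[_EVENT_VARS[col]] = events
    death = optional(PartialDate.parse, "death")
    if death is not None:
        obs[5] = death
    triple_raw = (row.get("surgery_types") or "").strip()
    if triple_raw:
        try:
            obs[8] = tuple(int(v) for v in triple_raw.split("|"))
        except ValueError:
            warnings.warn(f"row {rownum}: malformed surgery_types; set missing",
                          stacklevel=3)
    for col, var in (("chemo_dates", 9), ("radio_dates", 10)):
        dates = set()
        for part in _split(row.get(col, "")):
            try:
                dates.add(PartialDate.parse(part))
            except ValueError as exc:
                warnings.warn(f"row {rownum}: malformed date in {col} ({exc}); "
                              "dropped", stacklevel=3)
        if dates:
            obs[var] = dates
    depts = _split(row.get("departments", ""))
    if depts:
        obs[12] = set(depts)
    return SourceRecord(rid, kind, sex, birth, obs)


def read_source(path, source_kind: Source) -> List[SourceRecord]:
    """Parse one source CSV; duplicate ids and missing mandatory columns fail."""
    columns = CLINICAL_COLUMNS if source_kind is Source.CLINICAL else CLAIMS_COLUMNS
    records: List[SourceRecord] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for mandatory in ("record_id", "sex", "birth_date"):
            if mandatory not in header:
                raise ValueError(f"{path}: missing mandatory column {mandatory!r}")
        unknown = set(header) - set(columns)
        if unknown:
            warnings.warn(f"{path}: ignoring unknown columns {sorted(unknown)}",
                          stacklevel=2)
        for i, row in enumerate(reader, start=2):
            rec = _row_to_record(row, source_kind, i)
            if rec.record_id in seen:
                raise ValueError(f"{path}: duplicate record id {rec.record_id!r}")
            seen.add(rec.record_id)
            records.append(rec)
    return records


def write_source(path, records: Iterable[SourceRecord],
                 source_kind: Source) -> None:
    columns = CLINICAL_COLUMNS if source_kind is Source.CLINICAL else CLAIMS_COLUMNS
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for r in records:
            if r.source is not source_kind:
                raise ValueError(f"record {r.record_id} is not {source_kind}")
            writer.writerow(record_to_row(r))


# ---------------------------------------------------------------------------
# Result and truth tables
# ---------------------------------------------------------------------------


def write_links(path, result: LinkResult) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["clinical_id", "claims_id", "step_id", "score",
                         "adjusted_variables"])
        for l in result.links:
            writer.writerow([l.clinical_id, l.claims_id, l.step_id, l.score,
                             ";".join(str(v) for v in sorted(l.used_adjusted))])


def write_truth(path, truth: Mapping[str, str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["clinical_id", "claims_id"])
        for cid in sorted(truth):
            writer.writerow([cid, truth[cid]])


def read_truth(path) -> Dict[str, str]:
    truth: Dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            truth[row["clinical_id"]] = row["claims_id"]
    return truth


def read_links(path) -> Dict[str, str]:
    links: Dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            links[row["clinical_id"]] = row["claims_id"]
    return links
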