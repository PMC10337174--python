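"""Reading and writing the flat-file table formats.

All tables are header-first delimited text (delimiter sniffed from the header
line: tab if the header contains one, comma otherwise) with ISO-8601 dates.
Five event schemas are supported:

* ``registry``  — patient_id, birth_date, sex, registration_start,
  last_collection_date, transfer_out_date, death_date
* ``events``    — patient_id, event_date, code, term
* ``spells``    — one row per positioned diagnosis: patient_id,
  admission_date, discharge_date, episode_index, position, icd10
* ``deaths``    — one row per certified cause: patient_id, death_date,
  cause_rank (0 = underlying, 1..n = contributory), icd10
* ``imaging``   — patient_id, event_date, modality, body_region

Codelists are tab-separated with columns code, term, system, rating.
"""

from __future__ import annotations

import csv
from datetime import date
from pathlib import Path
from typing import Sequence

from .core import (
    BodyRegion,
    ClinicalEvent,
    CodeList,
    CodeSystem,
    DeathRecord,
    Episode,
    HospitalSpell,
    ImagingEvent,
    Modality,
    PatientRegistryRow,
    Rating,
    Sex,
    normalize_icd10,
)
from .errors import IntegrityError, SchemaError

__all__ = ["read_table", "write_table", "read_codelist", "write_codelist", "SCHEMAS"]

SCHEMAS = {
    "registry": ["patient_id", "birth_date", "sex", "registration_start",
                 "last_collection_date", "transfer_out_date", "death_date"],
    "events": ["patient_id", "event_date", "code", "term"],
    "spells": ["patient_id", "admission_date", "discharge_date",
               "episode_index", "position", "icd10"],
    "deaths": ["patient_id", "death_date", "cause_rank", "icd10"],
    "imaging": ["patient_id", "event_date", "modality", "body_region"],
}

CODELIST_COLUMNS = ["code", "term", "system", "rating"]


def _parse_date(text: str, line_no: int, column: str) -> date:
    try:
        return date.fromisoformat(text.strip())
    except ValueError as exc:
        raise IntegrityError(
            f"line {line_no}: column {column!r}: unparseable date {text!r}"
        ) from exc


def _parse_optional_date(text: str, line_no: int, column: str) -> date | None:
    if text is None or not text.strip():
        return None
    return _parse_date(text, line_no, column)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_rows(path: str | Path, expected: Sequence[str]):
    path = Path(path)
    with path.open(newline="") as handle:
        header_line = handle.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file")
        delim = _sniff_delimiter(header_line)
        header = [h.strip() for h in header_line.rstrip("\r\n").split(delim)]
        missing = [c for c in expected if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column {missing[0]!r}")
        reader = csv.reader(handle, delimiter=delim)
        for line_no, raw in enumerate(reader, start=2):
            if not raw or all(not cell.strip() for cell in raw):
                continue
            if len(raw) != len(header):
                raise SchemaError(
                    f"{path}: line {line_no}: expected {len(header)} fields, got {len(raw)}"
                )
            yield line_no, dict(zip(header, raw))


def _read_registry(path) -> list[PatientRegistryRow]:
    rows: list[PatientRegistryRow] = []
    seen: set[str] = set()
    for line_no, rec in _read_rows(path, SCHEMAS["registry"]):
        row = PatientRegistryRow(
            patient_id=rec["patient_id"].strip(),
            birth_date=_parse_date(rec["birth_date"], line_no, "birth_date"),
            sex=Sex(rec["sex"].strip().lower()),
            registration_start=_parse_date(
                rec["registration_start"], line_no, "registration_start"),
            last_collection_date=_parse_optional_date(
                rec["last_collection_date"], line_no, "last_collection_date"),
            transfer_out_date=_parse_optional_date(
                rec["transfer_out_date"], line_no, "transfer_out_date"),
            death_date=_parse_optional_date(rec["death_date"], line_no, "death_date"),
        )
        if row.patient_id in seen:
            raise IntegrityError(
                f"line {line_no}: duplicate patient_id {row.patient_id!r} in registry"
            )
        seen.add(row.patient_id)
        try:
            row.validate()
        except IntegrityError as exc:
            raise IntegrityError(f"line {line_no}: {exc}") from exc
        rows.append(row)
    return rows


def _read_events(path) -> list[ClinicalEvent]:
    rows = []
    for line_no, rec in _read_rows(path, SCHEMAS["events"]):
        event = ClinicalEvent(
            patient_id=rec["patient_id"].strip(),
            event_date=_parse_date(rec["event_date"], line_no, "event_date"),
            code=rec["code"].strip(),
            term=rec["term"].strip(),
        )
        try:
            event.validate()
        except IntegrityError as exc:
            raise IntegrityError(f"line {line_no}: {exc}") from exc
        rows.append(event)
    return rows


def _read_spells(path) -> list[HospitalSpell]:
    # One file row per diagnosis; group by (patient, admission, discharge),
    # then by episode_index, preserving first-appearance order.
    grouped: dict[tuple, dict[int, list[tuple[int, str]]]] = {}
    order: list[tuple] = []
    for line_no, rec in _read_rows(path, SCHEMAS["spells"]):
        key = (
            rec["patient_id"].strip(),
            _parse_date(rec["admission_date"], line_no, "admission_date"),
            _parse_date(rec["discharge_date"], line_no, "discharge_date"),
        )
        try:
            episode_index = int(rec["episode_index"])
            position = int(rec["position"])
        except ValueError as exc:
            raise IntegrityError(f"line {line_no}: non-integer episode/position") from exc
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        grouped[key].setdefault(episode_index, []).append(
            (position, normalize_icd10(rec["icd10"]))
        )
    spells = []
    for key in order:
        patient_id, admission, discharge = key
        episodes = tuple(
            Episode(episode_index=idx,
                    diagnoses=tuple(sorted(grouped[key][idx], key=lambda d: d[0])))
            for idx in sorted(grouped[key])
        )
        spell = HospitalSpell(patient_id, admission, discharge, episodes)
        spell.validate()
        spells.append(spell)
    return spells


def _read_deaths(path) -> list[DeathRecord]:
    grouped: dict[str, dict] = {}
    order: list[str] = []
    for line_no, rec in _read_rows(path, SCHEMAS["deaths"]):
        pid = rec["patient_id"].strip()
        try:
            rank = int(rec["cause_rank"])
        except ValueError as exc:
            raise IntegrityError(f"line {line_no}: non-integer cause_rank") from exc
        if pid not in grouped:
            grouped[pid] = {
                "death_date": _parse_date(rec["death_date"], line_no, "death_date"),
                "causes": [],
            }
            order.append(pid)
        grouped[pid]["causes"].append((rank, normalize_icd10(rec["icd10"])))
    records = []
    for pid in order:
        causes = sorted(grouped[pid]["causes"], key=lambda c: c[0])
        underlying = [c for r, c in causes if r == 0]
        if len(underlying) != 1:
            raise IntegrityError(
                f"patient {pid}: expected exactly one underlying cause (rank 0), "
                f"got {len(underlying)}"
            )
        record = DeathRecord(
            patient_id=pid,
            death_date=grouped[pid]["death_date"],
            underlying_cause=underlying[0],
            contributory_causes=tuple(c for r, c in causes if r > 0),
        )
        record.validate()
        records.append(record)
    return records


def _read_imaging(path) -> list[ImagingEvent]:
    rows = []
    for line_no, rec in _read_rows(path, SCHEMAS["imaging"]):
        rows.append(ImagingEvent(
            patient_id=rec["patient_id"].strip(),
            event_date=_parse_date(rec["event_date"], line_no, "event_date"),
            modality=Modality(rec["modality"].strip().upper()),
            body_region=BodyRegion(rec["body_region"].strip().lower()),
        ))
    return rows


_READERS = {
    "registry": _read_registry,
    "events": _read_events,
    "spells": _read_spells,
    "deaths": _read_deaths,
    "imaging": _read_imaging,
}


def read_table(path: str | Path, schema: str):
    """Read one of the five typed tables; rows are validated and order kept."""
    if schema not in _READERS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_READERS)}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return _READERS[schema](path)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, date):
        return value.isoformat()
    if isinstance(value, (Sex, BodyRegion, Modality, Rating, CodeSystem)):
        return value.value
    return str(value)


def write_table(rows, schema: str, path: str | Path) -> None:
    """Write typed rows back to canonical comma-delimited text."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    header = SCHEMAS[schema]
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(header)
        for row in rows:
            if schema == "registry":
                writer.writerow([_fmt(getattr(row, c)) for c in header])
            elif schema == "events":
                writer.writerow([row.patient_id, _fmt(row.event_date), row.code, row.term])
            elif schema == "spells":
                for episode in row.episodes:
                    for position, icd10 in episode.diagnoses:
                        writer.writerow([
                            row.patient_id, _fmt(row.admission_date),
                            _fmt(row.discharge_date), episode.episode_index,
                            position, icd10,
                        ])
            elif schema == "deaths":
                writer.writerow([row.patient_id, _fmt(row.death_date), 0,
                                 row.underlying_cause])
                for rank, cause in enumerate(row.contributory_causes, start=1):
                    writer.writerow([row.patient_id, _fmt(row.death_date), rank, cause])
            elif schema == "imaging":
                writer.writerow([row.patient_id, _fmt(row.event_date),
                                 row.modality.value, row.body_region.value])


def read_codelist(path: str | Path, name: str | None = None) -> CodeList:
    """Read a rated codelist TSV (columns code, term, system, rating).

    Rating tokens are case-folded, so "Yes"/"YES" are accepted.
    """
    path = Path(path)
    entries = []
    system = None
    for line_no, rec in _read_rows(path, CODELIST_COLUMNS):
        token = rec["rating"].strip().lower()
        try:
            rating = Rating(token)
        except ValueError as exc:
            raise SchemaError(
                f"{path}: line {line_no}: unknown rating token {rec['rating']!r}"
            ) from exc
        try:
            row_system = CodeSystem(rec["system"].strip().upper())
        except ValueError as exc:
            raise SchemaError(
                f"{path}: line {line_no}: unknown code system {rec['system']!r}"
            ) from exc
        if system is None:
            system = row_system
        elif system is not row_system:
            raise IntegrityError(f"{path}: mixed code systems in one list")
        entries.append((rec["code"].strip(), rec["term"].strip(), rating))
    return CodeList(name=name or path.stem, system=system or CodeSystem.SNOMED_LIKE,
                    entries=tuple(entries))


def write_codelist(codelist: CodeList, path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(CODELIST_COLUMNS)
        for code, term, rating in codelist.entries:
            writer.writerow([code, term, codelist.system.value, rating.value])
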