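"""Darwin Core occurrence records: parsing, validation, summaries, CSV.

The input fixture format mirrors how specimen records are printed in
taxonomic treatments: one block of ``field: value`` lines per record
(Darwin Core term names), blocks separated by blank lines, with the type
status (Holotype / Paratype / Other material) carried as ``typeStatus``.

Values are kept verbatim as text — coordinates keep their printed
precision, event dates keep their original shape — with typed accessors
on top.  :func:`normalize_event_date` understands the handful of date
dialects found on historical labels (``MM-YYYY``, ``DD-MM-YYYY`` and the
``DD/DD-MM-YYYY`` collecting-interval form); anything else stays
verbatim-only.
"""

from __future__ import annotations

import calendar
import csv
import io
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "OccurrenceRecord",
    "RecordError",
    "InvalidCoordinateError",
    "InvalidCountError",
    "parse_records",
    "summarize",
    "Summary",
    "export_csv",
    "parse_csv",
    "normalize_event_date",
]

# canonical column order for export: Darwin Core terms grouped the way the
# standard groups them (occurrence, taxon, location, identification, event,
# record-level); unknown fields follow in first-seen order
_CANONICAL_ORDER = [
    "typeStatus",
    "catalogNumber",
    "recordedBy",
    "individualCount",
    "sex",
    "lifeStage",
    "occurrenceID",
    "taxonID",
    "scientificName",
    "genus",
    "specificEpithet",
    "scientificNameAuthorship",
    "country",
    "stateProvince",
    "locality",
    "verbatimLocality",
    "verbatimElevation",
    "verbatimCoordinates",
    "decimalLatitude",
    "decimalLongitude",
    "georeferenceProtocol",
    "georeferenceRemarks",
    "identifiedBy",
    "dateIdentified",
    "eventID",
    "samplingProtocol",
    "eventDate",
    "habitat",
    "institutionID",
    "institutionCode",
    "basisOfRecord",
]


class RecordError(ValueError):
    pass


class InvalidCoordinateError(RecordError):
    pass


class InvalidCountError(RecordError):
    pass


@dataclass(frozen=True)
class OccurrenceRecord:
    """One specimen record as an ordered mapping of verbatim field values."""

    fields: tuple  # tuple of (term, value) pairs, order preserved

    def __post_init__(self) -> None:
        mapping = dict(self.fields)
        if len(mapping) != len(self.fields):
            raise RecordError("duplicate Darwin Core term within one record")
        count = mapping.get("individualCount")
        if count is not None:
            if not re.fullmatch(r"\d+", count):
                raise InvalidCountError(f"individualCount must be an integer: {count!r}")
            if int(count) < 1:
                raise InvalidCountError(f"individualCount must be >= 1: {count!r}")
        for term, lo, hi in (
            ("decimalLatitude", -90.0, 90.0),
            ("decimalLongitude", -180.0, 180.0),
        ):
            raw = mapping.get(term)
            if raw is not None:
                try:
                    value = float(raw)
                except ValueError:
                    raise InvalidCoordinateError(f"{term} is not a decimal: {raw!r}") from None
                if not lo <= value <= hi:
                    raise InvalidCoordinateError(f"{term} out of range: {raw}")

    def get(self, term: str, default: Optional[str] = None) -> Optional[str]:
        return dict(self.fields).get(term, default)

    def __getitem__(self, term: str) -> str:
        return dict(self.fields)[term]

    @property
    def type_status(self) -> Optional[str]:
        return self.get("typeStatus")

    @property
    def scientific_name(self) -> Optional[str]:
        return self.get("scientificName")

    @property
    def individual_count(self) -> int:
        raw = self.get("individualCount")
        return int(raw) if raw is not None else 1

    @property
    def decimal_latitude(self) -> Optional[float]:
        raw = self.get("decimalLatitude")
        return float(raw) if raw is not None else None

    @property
    def decimal_longitude(self) -> Optional[float]:
        raw = self.get("decimalLongitude")
        return float(raw) if raw is not None else None

    @property
    def event_date_interval(self) -> Optional[str]:
        raw = self.get("eventDate")
        return normalize_event_date(raw) if raw else None


def parse_records(source: str) -> list[OccurrenceRecord]:
    """Parse blank-line-separated ``field: value`` blocks into records.

    Unknown field names are preserved as-is; ``occurrenceID`` values must
    be unique across the parsed set.
    """
    records: list[OccurrenceRecord] = []
    seen_ids: set[str] = set()
    for block in re.split(r"\n\s*\n", source.strip()):
        if not block.strip():
            continue
        pairs: list[tuple[str, str]] = []
        for line in block.split("\n"):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, sep, value = line.partition(":")
            if not sep:
                raise RecordError(f"not a 'field: value' line: {line!r}")
            pairs.append((term.strip(), value.strip()))
        record = OccurrenceRecord(tuple(pairs))
        occurrence_id = record.get("occurrenceID")
        if occurrence_id:
            if occurrence_id in seen_ids:
                raise RecordError(f"duplicate occurrenceID: {occurrence_id}")
            seen_ids.add(occurrence_id)
        records.append(record)
    return records


@dataclass(frozen=True)
class Summary:
    record_count: int
    records_by_type_status: dict
    total_individuals: int
    individuals_by_species: dict


def summarize(records: Sequence[OccurrenceRecord]) -> Summary:
    """Record counts by type status plus individual tallies."""
    by_status: dict[str, int] = {}
    by_species: dict[str, int] = {}
    total = 0
    for record in records:
        status = record.type_status or "Unstated"
        by_status[status] = by_status.get(status, 0) + 1
        total += record.individual_count
        name = record.scientific_name or "?"
        by_species[name] = by_species.get(name, 0) + record.individual_count
    return Summary(
        record_count=len(records),
        records_by_type_status=by_status,
        total_individuals=total,
        individuals_by_species=by_species,
    )


def _column_order(records: Sequence[OccurrenceRecord]) -> list[str]:
    present: list[str] = []
    for record in records:
        for term, _ in record.fields:
            if term not in present:
                present.append(term)
    known = [t for t in _CANONICAL_ORDER if t in present]
    extras = [t for t in present if t not in _CANONICAL_ORDER]
    return known + extras


def export_csv(records: Sequence[OccurrenceRecord]) -> str:
    """CSV with canonical Darwin Core headers; values stay verbatim."""
    columns = _column_order(records)
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(columns)
    for record in records:
        mapping = dict(record.fields)
        writer.writerow([mapping.get(term, "") for term in columns])
    return buffer.getvalue()


def parse_csv(text: str) -> list[OccurrenceRecord]:
    """Inverse of :func:`export_csv`; empty cells mean 'field absent'."""
    reader = csv.reader(io.StringIO(text))
    rows = list(reader)
    if not rows:
        return []
    header = rows[0]
    records = []
    for row in rows[1:]:
        pairs = tuple(
            (term, value) for term, value in zip(header, row) if value != ""
        )
        records.append(OccurrenceRecord(pairs))
    return records


_MONTH_YEAR = re.compile(r"^(\d{2})-(\d{4})$")
_DAY_MONTH_YEAR = re.compile(r"^(\d{1,2})-(\d{1,2})-(\d{4})$")
_DAY_RANGE = re.compile(r"^(\d{1,2})/(\d{1,2})-(\d{1,2})-(\d{4})$")


def normalize_event_date(verbatim: str) -> Optional[str]:
    """ISO-8601 date or interval for the recognized label-date dialects.

    ``"12-2006"`` (month-year) becomes the full-month interval
    ``2006-12-01/2006-12-31``; ``"23-11-2006"`` a single day;
    ``"03/07-03-2022"`` the day range ``2022-03-03/2022-03-07``.  Returns
    ``None`` for anything else (the verbatim value is kept by the caller).
    """
    verbatim = verbatim.strip()
    match = _MONTH_YEAR.match(verbatim)
    if match:
        month, year = int(match.group(1)), int(match.group(2))
        if 1 <= month <= 12:
            last = calendar.monthrange(year, month)[1]
            return f"{year:04d}-{month:02d}-01/{year:04d}-{month:02d}-{last:02d}"
        return None
    match = _DAY_RANGE.match(verbatim)
    if match:
        day_a, day_b, month, year = map(int, match.groups())
        if _valid(year, month, day_a) and _valid(year, month, day_b):
            lo, hi = sorted((day_a, day_b))
            return (
                f"{year:04d}-{month:02d}-{lo:02d}/{year:04d}-{month:02d}-{hi:02d}"
            )
        return None
    match = _DAY_MONTH_YEAR.match(verbatim)
    if match:
        day, month, year = map(int, match.groups())
        if _valid(year, month, day):
            return f"{year:04d}-{month:02d}-{day:02d}"
    return None


def _valid(year: int, month: int, day: int) -> bool:
    return 1 <= month <= 12 and 1 <= day <= calendar.monthrange(year, month)[1]
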