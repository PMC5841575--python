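"""Domain model for the searchable population registry.

An HDSS (health and demographic surveillance system) registry is a
household-based longitudinal roster: each row is one *residency episode*
of one person — a dated interval of residence in one household.  A person
who moved away and returned therefore appears under several record IDs.
Records carry up to three names, sex, a (possibly partial) date of birth,
village and sub-village, the episode's calendar years, a household ID and
the names of the ten-cell leader (TCL), a community leader responsible
for a block of roughly ten households.

Identity searches issued at a clinic are represented by
:class:`SearchQuery`, mirroring the fields a patient can report,
including the names of one co-resident household member.

All names are stored uppercased and whitespace-trimmed; missing values
are empty CSV cells.  A reported residence outside the surveillance area
is encoded with the sentinel village :data:`OUTSIDE_AREA` and makes the
query unsearchable (no registry record can exist for it).
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import IntegrityError, LookupError_, SchemaError

__all__ = [
    "OUTSIDE_AREA",
    "RegistryRecord",
    "Registry",
    "SearchQuery",
    "load_registry",
    "write_registry",
    "load_queries",
    "write_queries",
    "REGISTRY_COLUMNS",
    "QUERY_COLUMNS",
]

#: Sentinel village value marking a residency episode outside the
#: surveillance area (such episodes have no registry record by definition).
OUTSIDE_AREA = "OUTSIDE"

REGISTRY_COLUMNS = [
    "record_id", "name1", "name2", "name3", "sex",
    "birth_year", "birth_month", "birth_day",
    "village", "subvillage", "res_start_year", "res_end_year",
    "household_id", "tcl_name1", "tcl_name2", "tcl_name3",
]

QUERY_COLUMNS = [
    "name1", "name2", "name3", "sex",
    "birth_year", "birth_month", "birth_day",
    "village", "subvillage", "res_start_year", "res_end_year",
    "hh_name1", "hh_name2", "hh_name3",
    "tcl_name1", "tcl_name2", "tcl_name3",
    "first_residence_date",
]


def _norm_name(token: str) -> str:
    return " ".join(token.split()).upper()


def _norm_names(tokens: Iterable[str]) -> tuple[str, ...]:
    out = []
    for t in tokens:
        t = _norm_name(t)
        if t:
            out.append(t)
    return tuple(out)


@dataclass(frozen=True)
class RegistryRecord:
    """One residency episode of one person in the registry."""

    record_id: str
    names: tuple[str, ...]
    sex: Optional[str]
    birth_year: Optional[int]
    birth_month: Optional[int]
    birth_day: Optional[int]
    village: str
    subvillage: Optional[str]
    residency_start_year: int
    residency_end_year: Optional[int]  # None = open episode
    household_id: str
    tcl_names: tuple[str, ...] = ()

    def validate(self) -> None:
        if not self.names or not all(self.names):
            raise IntegrityError(f"record {self.record_id!r}: needs >=1 non-empty name")
        if len(self.names) > 3:
            raise IntegrityError(f"record {self.record_id!r}: more than 3 names")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise IntegrityError(f"record {self.record_id!r}: sex must be M or F")
        if self.birth_month is not None and not 1 <= self.birth_month <= 12:
            raise IntegrityError(f"record {self.record_id!r}: bad birth_month")
        if self.birth_day is not None and not 1 <= self.birth_day <= 31:
            raise IntegrityError(f"record {self.record_id!r}: bad birth_day")
        if (
            self.residency_end_year is not None
            and self.residency_start_year > self.residency_end_year
        ):
            raise IntegrityError(
                f"record {self.record_id!r}: residency start after end"
            )


class Registry:
    """A cross-sectional extract of the registry, indexed by record ID
    and by household.

    ``extract_date`` is the date the extract was produced; patients whose
    first residence postdates it cannot have a record yet ("recent
    residents")."""

    def __init__(
        self,
        records: Sequence[RegistryRecord],
        extract_date: Optional[_dt.date] = None,
    ):
        self.records: list[RegistryRecord] = list(records)
        self.extract_date = extract_date
        self._by_id: dict[str, RegistryRecord] = {}
        self.households: dict[str, list[str]] = {}
        for rec in self.records:
            rec.validate()
            if rec.record_id in self._by_id:
                raise IntegrityError(f"duplicate record_id {rec.record_id!r}")
            self._by_id[rec.record_id] = rec
            self.households.setdefault(rec.household_id, []).append(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def get(self, record_id: str) -> RegistryRecord:
        try:
            return self._by_id[record_id]
        except KeyError:
            raise LookupError_(f"unknown record_id {record_id!r}") from None

    def household_members(self, record_id: str) -> list[tuple[str, ...]]:
        """Name lists of every record sharing the household of ``record_id``
        (the record itself included, as the fieldworker sees the full roster)."""
        rec = self.get(record_id)
        return [
            self._by_id[rid].names for rid in self.households[rec.household_id]
        ]

    def household_conames(self, record_id: str) -> tuple[str, ...]:
        """Flattened name tokens of the *other* members of the record's
        household — the pool a reported co-resident name is compared to."""
        rec = self.get(record_id)
        tokens: list[str] = []
        for rid in self.households[rec.household_id]:
            if rid != record_id:
                tokens.extend(self._by_id[rid].names)
        return tuple(tokens)


@dataclass(frozen=True)
class SearchQuery:
    """Identifiers reported by a patient for one search attempt."""

    names: tuple[str, ...]
    sex: Optional[str] = None
    birth_year: Optional[int] = None
    birth_month: Optional[int] = None
    birth_day: Optional[int] = None
    village: Optional[str] = None
    subvillage: Optional[str] = None
    residency_start_year: Optional[int] = None
    residency_end_year: Optional[int] = None
    hh_member_names: tuple[str, ...] = ()
    tcl_names: tuple[str, ...] = ()
    first_residence_date: Optional[_dt.date] = None

    @property
    def searchable(self) -> bool:
        """A query is runnable iff it has at least one name and does not
        report residence outside the surveillance area."""
        return bool(self.names) and self.village != OUTSIDE_AREA

    def normalized(self) -> "SearchQuery":
        return replace(
            self,
            names=_norm_names(self.names),
            hh_member_names=_norm_names(self.hh_member_names),
            tcl_names=_norm_names(self.tcl_names),
            village=_norm_name(self.village) if self.village else self.village,
            subvillage=_norm_name(self.subvillage) if self.subvillage else None,
        )


# ---------------------------------------------------------------------------
# CSV I/O

def _opt_int(cell: str, *, what: str, row: int) -> Optional[int]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError:
        raise SchemaError(f"row {row}: {what} is not an integer: {cell!r}") from None


def _fmt(v) -> str:
    return "" if v is None else str(v)


def load_registry(path, extract_date: Optional[_dt.date] = None) -> Registry:
    """Read a registry CSV (documented header) into a :class:`Registry`.

    Raises :class:`SchemaError` on missing columns and
    :class:`IntegrityError` on duplicate record IDs.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected header")
        missing = set(REGISTRY_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        records = []
        for i, row in enumerate(reader, start=2):
            names = _norm_names(row[f"name{k}"] for k in (1, 2, 3))
            tcl = _norm_names(row[f"tcl_name{k}"] for k in (1, 2, 3))
            sex = row["sex"].strip().upper() or None
            start = _opt_int(row["res_start_year"], what="res_start_year", row=i)
            if start is None:
                raise SchemaError(f"row {i}: res_start_year is required")
            records.append(
                RegistryRecord(
                    record_id=row["record_id"].strip(),
                    names=names,
                    sex=sex,
                    birth_year=_opt_int(row["birth_year"], what="birth_year", row=i),
                    birth_month=_opt_int(row["birth_month"], what="birth_month", row=i),
                    birth_day=_opt_int(row["birth_day"], what="birth_day", row=i),
                    village=_norm_name(row["village"]),
                    subvillage=_norm_name(row["subvillage"]) or None,
                    residency_start_year=start,
                    residency_end_year=_opt_int(
                        row["res_end_year"], what="res_end_year", row=i
                    ),
                    household_id=row["household_id"].strip(),
                    tcl_names=tcl,
                )
            )
    return Registry(records, extract_date=extract_date)


def write_registry(registry: Registry, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(REGISTRY_COLUMNS)
        for r in registry:
            names = list(r.names) + [""] * (3 - len(r.names))
            tcl = list(r.tcl_names) + [""] * (3 - len(r.tcl_names))
            w.writerow(
                [
                    r.record_id, *names, _fmt(r.sex),
                    _fmt(r.birth_year), _fmt(r.birth_month), _fmt(r.birth_day),
                    r.village, _fmt(r.subvillage),
                    r.residency_start_year, _fmt(r.residency_end_year),
                    r.household_id, *tcl,
                ]
            )


def load_queries(path) -> list[SearchQuery]:
    """Read a batch-query CSV (header :data:`QUERY_COLUMNS`; an extra
    ``true_record_id`` column, if present, is ignored here)."""
    queries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected header")
        missing = set(QUERY_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            frd = row["first_residence_date"].strip()
            queries.append(
                SearchQuery(
                    names=_norm_names(row[f"name{k}"] for k in (1, 2, 3)),
                    sex=row["sex"].strip().upper() or None,
                    birth_year=_opt_int(row["birth_year"], what="birth_year", row=i),
                    birth_month=_opt_int(row["birth_month"], what="birth_month", row=i),
                    birth_day=_opt_int(row["birth_day"], what="birth_day", row=i),
                    village=_norm_name(row["village"]) or None,
                    subvillage=_norm_name(row["subvillage"]) or None,
                    residency_start_year=_opt_int(
                        row["res_start_year"], what="res_start_year", row=i
                    ),
                    residency_end_year=_opt_int(
                        row["res_end_year"], what="res_end_year", row=i
                    ),
                    hh_member_names=_norm_names(row[f"hh_name{k}"] for k in (1, 2, 3)),
                    tcl_names=_norm_names(row[f"tcl_name{k}"] for k in (1, 2, 3)),
                    first_residence_date=(
                        _dt.date.fromisoformat(frd) if frd else None
                    ),
                )
            )
    return queries


def write_queries(queries: Sequence[SearchQuery], path, truths=None) -> None:
    """Write queries to CSV; ``truths`` (optional, parallel list of record
    IDs or None) adds a ``true_record_id`` column for evaluation sets."""
    cols = QUERY_COLUMNS + (["true_record_id"] if truths is not None else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for idx, q in enumerate(queries):
            names = list(q.names) + [""] * (3 - len(q.names))
            hh = list(q.hh_member_names) + [""] * (3 - len(q.hh_member_names))
            tcl = list(q.tcl_names) + [""] * (3 - len(q.tcl_names))
            row = [
                *names, _fmt(q.sex),
                _fmt(q.birth_year), _fmt(q.birth_month), _fmt(q.birth_day),
                _fmt(q.village), _fmt(q.subvillage),
                _fmt(q.residency_start_year), _fmt(q.residency_end_year),
                *hh, *tcl,
                q.first_residence_date.isoformat() if q.first_residence_date else "",
            ]
            if truths is not None:
                row.append(_fmt(truths[idx]))
            w.writerow(row)


def household_members(registry: Registry, record_id: str) -> list[tuple[str, ...]]:
    """Module-level convenience mirroring :meth:`Registry.household_members`."""
    return registry.household_members(record_id)
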