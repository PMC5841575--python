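"""Back-end integrity checks on the accumulated match data.

A patient (a cluster of clinic IDs) legitimately matches several
registry records when they held several residency episodes.  Certain
combinations, however, are implausible and flag a likely wrong match:
two matched records whose birth years differ by more than 10 years, of
conflicting sex, sharing a household (separate episodes of one person
live in *different* households), or with overlapping residency episodes
(one person cannot reside in two places at once).  Flags are reported
for manual review, never auto-deleted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .registry import Registry, RegistryRecord
from .store import SessionStore

__all__ = [
    "AGE_CONFLICT",
    "SEX_CONFLICT",
    "SAME_HOUSEHOLD",
    "OVERLAP",
    "DANGLING_REFERENCE",
    "QCFlag",
    "flag_suspect_matches",
    "episodes_overlap",
]

AGE_CONFLICT = "AGE_CONFLICT"
SEX_CONFLICT = "SEX_CONFLICT"
SAME_HOUSEHOLD = "SAME_HOUSEHOLD"
OVERLAP = "OVERLAP"
DANGLING_REFERENCE = "DANGLING_REFERENCE"

_AGE_GAP_YEARS = 10


@dataclass(frozen=True)
class QCFlag:
    """One suspect pair of matched records for one patient cluster."""

    clinic_ids: tuple[tuple[str, str], ...]
    record_pair: tuple[str, str]  # sorted record IDs; second empty if dangling
    flags: tuple[str, ...]


def episodes_overlap(a: RegistryRecord, b: RegistryRecord) -> bool:
    """True iff one record's residency starts before the other's ends.

    A missing end year means an open episode, overlapping anything that
    starts later.  Symmetric in the pair; back-to-back episodes (one
    ending the year the other starts) do not overlap."""
    end_a = a.residency_end_year if a.residency_end_year is not None else float("inf")
    end_b = b.residency_end_year if b.residency_end_year is not None else float("inf")
    return a.residency_start_year < end_b and b.residency_start_year < end_a


def _pair_flags(a: RegistryRecord, b: RegistryRecord) -> list[str]:
    flags = []
    if (
        a.birth_year is not None
        and b.birth_year is not None
        and abs(a.birth_year - b.birth_year) > _AGE_GAP_YEARS
    ):
        flags.append(AGE_CONFLICT)
    if a.sex is not None and b.sex is not None and a.sex != b.sex:
        flags.append(SEX_CONFLICT)
    if a.household_id == b.household_id:
        flags.append(SAME_HOUSEHOLD)
    if episodes_overlap(a, b):
        flags.append(OVERLAP)
    return flags


def flag_suspect_matches(store: SessionStore, registry: Registry) -> list[QCFlag]:
    """Scan every patient cluster matched to two or more registry records
    and report implausible pairs; a single-record patient is never flagged.

    A match pointing at a record ID absent from the registry yields a
    DANGLING_REFERENCE flag for that ID."""
    out: list[QCFlag] = []
    for cluster in store.clinic_id_clusters():
        ids = tuple(sorted(cluster["clinic_ids"]))
        matched = sorted(cluster["matched_record_ids"])
        records = []
        for rid in matched:
            if rid in registry:
                records.append(registry.get(rid))
            else:
                out.append(
                    QCFlag(clinic_ids=ids, record_pair=(rid, ""), flags=(DANGLING_REFERENCE,))
                )
        if len(records) < 2:
            continue
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                flags = _pair_flags(records[i], records[j])
                if flags:
                    pair = tuple(
                        sorted((records[i].record_id, records[j].record_id))
                    )
                    out.append(
                        QCFlag(clinic_ids=ids, record_pair=pair, flags=tuple(flags))
                    )
    return out
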