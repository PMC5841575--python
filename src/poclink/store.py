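"""Four-table session store: Registry (search attempts), Matches, Notes,
Visits.

Every row is stamped with the compound key (machine name, session ID,
record number).  A new Registry row is written for every search attempt;
matches, free-text match notes and visit dates reference that key.  On a
return visit the patient is found again by any clinic identifier entered
in a previous session, and identifiers are linked transitively: a
session that recorded both an ANC and an HTC number ties those two IDs
to the same person for all later lookups.

Storage is a single-file sqlite database (or in-memory for tests).  Each
machine exports a JSON backup at the end of the day; backups from all
machines are merged by key, so the merge is idempotent and
order-independent, with payload conflicts resolved newest-first.  An
optional passphrase encrypts the backup container at rest (a stdlib
PBKDF2 + SHA-256 keystream + HMAC construction — obfuscation for field
laptops, not a vetted AEAD; off by default).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import hmac as _hmac
import json
import os
import sqlite3
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import InputError, IntegrityError, LookupError_
from .identifiers import ClinicID, Session, SessionKey, validate_clinic_id
from .linkage import CandidateMatch
from .registry import SearchQuery

__all__ = [
    "SessionStore",
    "PatientSummary",
    "MergeConflict",
    "encrypt_container",
    "decrypt_container",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS registry_rows (
    machine TEXT NOT NULL,
    session_id TEXT NOT NULL,
    record_number TEXT NOT NULL,
    clinic_ids TEXT NOT NULL,       -- JSON list of [clinic, value]
    query_json TEXT NOT NULL,       -- all SearchQuery fields as entered
    first_residence_date TEXT,
    recent_resident INTEGER NOT NULL DEFAULT 0,
    created_at TEXT NOT NULL,
    PRIMARY KEY (machine, session_id, record_number)
);
CREATE TABLE IF NOT EXISTS matches (
    machine TEXT NOT NULL,
    session_id TEXT NOT NULL,
    record_number TEXT NOT NULL,
    hdss_record_id TEXT NOT NULL,
    score REAL NOT NULL,
    rank INTEGER NOT NULL,
    created_at TEXT NOT NULL,
    PRIMARY KEY (machine, session_id, record_number, hdss_record_id)
);
CREATE TABLE IF NOT EXISTS notes (
    machine TEXT NOT NULL,
    session_id TEXT NOT NULL,
    record_number TEXT NOT NULL,
    note TEXT NOT NULL,
    created_at TEXT NOT NULL,
    PRIMARY KEY (machine, session_id, record_number, note, created_at)
);
CREATE TABLE IF NOT EXISTS visits (
    machine TEXT NOT NULL,
    session_id TEXT NOT NULL,
    record_number TEXT NOT NULL,
    visit_date TEXT NOT NULL,
    created_at TEXT NOT NULL,
    PRIMARY KEY (machine, session_id, record_number, visit_date)
);
"""

_TABLES = ("registry_rows", "matches", "notes", "visits")

# primary-key column count per table (prefix of the column list)
_PK_COLS = {
    "registry_rows": 3,
    "matches": 4,
    "notes": 5,
    "visits": 4,
}

_COLUMNS = {
    "registry_rows": [
        "machine", "session_id", "record_number", "clinic_ids", "query_json",
        "first_residence_date", "recent_resident", "created_at",
    ],
    "matches": [
        "machine", "session_id", "record_number", "hdss_record_id",
        "score", "rank", "created_at",
    ],
    "notes": ["machine", "session_id", "record_number", "note", "created_at"],
    "visits": ["machine", "session_id", "record_number", "visit_date", "created_at"],
}


def _query_to_json(q: SearchQuery) -> str:
    d = {
        "names": list(q.names),
        "sex": q.sex,
        "birth_year": q.birth_year,
        "birth_month": q.birth_month,
        "birth_day": q.birth_day,
        "village": q.village,
        "subvillage": q.subvillage,
        "residency_start_year": q.residency_start_year,
        "residency_end_year": q.residency_end_year,
        "hh_member_names": list(q.hh_member_names),
        "tcl_names": list(q.tcl_names),
        "first_residence_date": (
            q.first_residence_date.isoformat() if q.first_residence_date else None
        ),
    }
    return json.dumps(d, sort_keys=True)


@dataclass(frozen=True)
class PatientSummary:
    """What the fieldworker sees when a known clinic ID is entered."""

    status: str  # "Matched" | "Not matched" | "New"
    clinic_ids: tuple[tuple[str, str], ...]
    matches: tuple[dict, ...]
    notes: tuple[str, ...]  # most recent first
    visit_dates: tuple[str, ...]


@dataclass(frozen=True)
class MergeConflict:
    table: str
    key: tuple
    kept_created_at: str
    dropped_created_at: str


class SessionStore:
    """The embedded four-table store for one machine (or the merged set)."""

    def __init__(self, path: str = ":memory:", extract_date: Optional[_dt.date] = None):
        self.path = path
        self.extract_date = extract_date
        self._conn = sqlite3.connect(path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- writes -----------------------------------------------------------

    def record_search_attempt(
        self,
        session: Session,
        query: SearchQuery,
        clinic_ids: Sequence[ClinicID | tuple[str, str]],
        now: Optional[_dt.datetime] = None,
    ) -> SessionKey:
        """Append one Registry row for a search attempt; returns its key.

        Requires at least one clinic ID; an invalid ID is rejected before
        anything is written."""
        if not clinic_ids:
            raise InputError("at least one clinic ID is required")
        validated: list[ClinicID] = []
        for cid in clinic_ids:
            if not isinstance(cid, ClinicID):
                cid = validate_clinic_id(cid[0], cid[1])
            if not cid.valid:
                raise InputError(
                    f"invalid {cid.clinic} ID {cid.value!r}: rejected before write"
                )
            validated.append(cid)
        key = session.key(session.next_record_number())
        recent = bool(
            query.first_residence_date
            and self.extract_date
            and query.first_residence_date > self.extract_date
        )
        created = (now or _dt.datetime.now()).isoformat()
        self._conn.execute(
            "INSERT INTO registry_rows VALUES (?,?,?,?,?,?,?,?)",
            (
                *key.as_tuple(),
                json.dumps([[c.clinic, c.value] for c in validated]),
                _query_to_json(query),
                (
                    query.first_residence_date.isoformat()
                    if query.first_residence_date
                    else None
                ),
                int(recent),
                created,
            ),
        )
        self._conn.commit()
        return key

    def _require_key(self, key: SessionKey) -> None:
        cur = self._conn.execute(
            "SELECT 1 FROM registry_rows WHERE machine=? AND session_id=? "
            "AND record_number=?",
            key.as_tuple(),
        )
        if cur.fetchone() is None:
            raise LookupError_(f"no registry row for key {key}")

    def save_match(
        self,
        key: SessionKey,
        candidate: CandidateMatch,
        now: Optional[_dt.datetime] = None,
    ) -> None:
        self._require_key(key)
        self._conn.execute(
            "INSERT OR REPLACE INTO matches VALUES (?,?,?,?,?,?,?)",
            (
                *key.as_tuple(),
                candidate.record_id,
                candidate.score,
                candidate.rank,
                (now or _dt.datetime.now()).isoformat(),
            ),
        )
        self._conn.commit()

    def save_note(
        self, key: SessionKey, text: str, now: Optional[_dt.datetime] = None
    ) -> None:
        if not text or not text.strip():
            raise InputError("match note must be non-empty")
        self._require_key(key)
        self._conn.execute(
            "INSERT OR IGNORE INTO notes VALUES (?,?,?,?,?)",
            (*key.as_tuple(), text, (now or _dt.datetime.now()).isoformat()),
        )
        self._conn.commit()

    def log_visit(
        self, key: SessionKey, date: _dt.date, now: Optional[_dt.datetime] = None
    ) -> None:
        if not isinstance(date, _dt.date):
            raise InputError(f"visit date must be a date, got {type(date).__name__}")
        self._require_key(key)
        self._conn.execute(
            "INSERT OR IGNORE INTO visits VALUES (?,?,?,?,?)",
            (*key.as_tuple(), date.isoformat(), (now or _dt.datetime.now()).isoformat()),
        )
        self._conn.commit()

    # -- reads ------------------------------------------------------------

    def _rows(self, table: str) -> list[tuple]:
        cols = ", ".join(_COLUMNS[table])
        pk = ", ".join(_COLUMNS[table][: _PK_COLS[table]])
        return self._conn.execute(
            f"SELECT {cols} FROM {table} ORDER BY {pk}"
        ).fetchall()

    def last_session_start(self, machine: str):
        """Start time of the newest stored session on ``machine`` (or None);
        lets a session allocator avoid reusing a persisted session ID."""
        from .identifiers import parse_session_id

        cur = self._conn.execute(
            "SELECT MAX(session_id) FROM registry_rows WHERE machine=?", (machine,)
        )
        (value,) = cur.fetchone()
        return parse_session_id(value) if value else None

    def row_counts(self) -> dict:
        return {t: len(self._rows(t)) for t in _TABLES}

    def clinic_id_clusters(self) -> list[dict]:
        """Patient clusters: registry-row keys linked transitively by any
        shared clinic identifier (union-find over ID values)."""
        rows = self._rows("registry_rows")
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        row_ids: list[tuple[tuple, list[tuple[str, str]]]] = []
        for r in rows:
            key = (r[0], r[1], r[2])
            ids = [tuple(p) for p in json.loads(r[3])]
            row_ids.append((key, ids))
            for _, value in ids:
                parent.setdefault(value, value)
            for (_, v1), (_, v2) in zip(ids, ids[1:]):
                union(v1, v2)
        clusters: dict[str, dict] = {}
        for key, ids in row_ids:
            if not ids:
                continue
            root = find(ids[0][1])
            c = clusters.setdefault(
                root, {"clinic_ids": set(), "keys": [], "matched_record_ids": set()}
            )
            c["clinic_ids"].update(ids)
            c["keys"].append(key)
        for c in clusters.values():
            placeholders = ",".join("(?,?,?)" for _ in c["keys"])
            flat = [x for k in c["keys"] for x in k]
            cur = self._conn.execute(
                "SELECT hdss_record_id FROM matches "
                f"WHERE (machine, session_id, record_number) IN ({placeholders})",
                flat,
            )
            c["matched_record_ids"].update(v for (v,) in cur.fetchall())
        return list(clusters.values())

    def lookup_by_clinic_id(self, clinic_id_value: str) -> PatientSummary:
        """Match status, prior matches, notes (most recent first) and visit
        dates for the patient linked to ``clinic_id_value``."""
        clinic_id_value = "".join(clinic_id_value.split())
        for cluster in self.clinic_id_clusters():
            if any(v == clinic_id_value for _, v in cluster["clinic_ids"]):
                keys = cluster["keys"]
                placeholders = ",".join("(?,?,?)" for _ in keys)
                flat = [x for k in keys for x in k]
                matches = self._conn.execute(
                    "SELECT hdss_record_id, score, rank FROM matches "
                    f"WHERE (machine, session_id, record_number) IN ({placeholders})",
                    flat,
                ).fetchall()
                notes = self._conn.execute(
                    "SELECT note FROM notes "
                    f"WHERE (machine, session_id, record_number) IN ({placeholders}) "
                    "ORDER BY created_at DESC",
                    flat,
                ).fetchall()
                visits = self._conn.execute(
                    "SELECT DISTINCT visit_date FROM visits "
                    f"WHERE (machine, session_id, record_number) IN ({placeholders}) "
                    "ORDER BY visit_date",
                    flat,
                ).fetchall()
                status = "Matched" if matches else "Not matched"
                return PatientSummary(
                    status=status,
                    clinic_ids=tuple(sorted(cluster["clinic_ids"])),
                    matches=tuple(
                        {"hdss_record_id": r, "score": s, "rank": k}
                        for r, s, k in matches
                    ),
                    notes=tuple(n for (n,) in notes),
                    visit_dates=tuple(v for (v,) in visits),
                )
        return PatientSummary(
            status="New", clinic_ids=(), matches=(), notes=(), visit_dates=()
        )

    def check_referential_integrity(self) -> list[str]:
        """Keys in Matches/Notes/Visits with no Registry row (should be empty)."""
        problems = []
        for table in ("matches", "notes", "visits"):
            cur = self._conn.execute(
                f"SELECT t.machine, t.session_id, t.record_number FROM {table} t "
                "LEFT JOIN registry_rows r USING (machine, session_id, record_number) "
                "WHERE r.machine IS NULL"
            )
            for row in cur.fetchall():
                problems.append(f"{table}: dangling key {row}")
        return problems

    # -- backup / merge ----------------------------------------------------

    def export_backup(self, path, passphrase: Optional[str] = None) -> None:
        """Write all four tables to a JSON backup (optionally encrypted)."""
        payload = {t: [list(r) for r in self._rows(t)] for t in _TABLES}
        blob = json.dumps(payload, sort_keys=True).encode("utf-8")
        if passphrase:
            blob = encrypt_container(blob, passphrase)
        with open(path, "wb") as fh:
            fh.write(blob)

    def import_merge(
        self, *backup_paths, passphrase: Optional[str] = None
    ) -> list[MergeConflict]:
        """Merge JSON backups into this store.

        Rows are unioned by primary key; identical rows collapse; rows
        with the same key but different payloads are a conflict — the
        one with the newest ``created_at`` wins (ties broken on the
        serialized payload, so the merge is order-independent)."""
        conflicts: list[MergeConflict] = []
        for path in backup_paths:
            with open(path, "rb") as fh:
                blob = fh.read()
            if passphrase:
                blob = decrypt_container(blob, passphrase)
            try:
                payload = json.loads(blob.decode("utf-8"))
            except (UnicodeDecodeError, json.JSONDecodeError) as exc:
                raise InputError(f"{path}: not a readable backup: {exc}") from None
            for table in _TABLES:
                cols = _COLUMNS[table]
                npk = _PK_COLS[table]
                for row in payload.get(table, []):
                    if len(row) != len(cols):
                        raise InputError(f"{path}: malformed row in {table}")
                    key = tuple(row[:npk])
                    where = " AND ".join(f"{c}=?" for c in cols[:npk])
                    existing = self._conn.execute(
                        f"SELECT {', '.join(cols)} FROM {table} WHERE {where}", key
                    ).fetchone()
                    if existing is None:
                        self._conn.execute(
                            f"INSERT INTO {table} VALUES "
                            f"({','.join('?' * len(cols))})",
                            row,
                        )
                        continue
                    if list(existing) == row:
                        continue
                    # conflict: newest created_at wins; deterministic tiebreak
                    new_sort = (row[-1], json.dumps(row))
                    old_sort = (existing[-1], json.dumps(list(existing)))
                    if new_sort > old_sort:
                        sets = ", ".join(f"{c}=?" for c in cols[npk:])
                        self._conn.execute(
                            f"UPDATE {table} SET {sets} WHERE {where}",
                            [*row[npk:], *key],
                        )
                        conflicts.append(
                            MergeConflict(table, key, row[-1], existing[-1])
                        )
                    else:
                        conflicts.append(
                            MergeConflict(table, key, existing[-1], row[-1])
                        )
        self._conn.commit()
        return conflicts

    def export_csv(self, directory) -> dict:
        """Write registry.csv, matches.csv, notes.csv, visits.csv with
        stable column order; returns {table: path}."""
        import csv as _csv

        os.makedirs(directory, exist_ok=True)
        out = {}
        names = {
            "registry_rows": "registry.csv",
            "matches": "matches.csv",
            "notes": "notes.csv",
            "visits": "visits.csv",
        }
        for table in _TABLES:
            path = os.path.join(directory, names[table])
            with open(path, "w", newline="", encoding="utf-8") as fh:
                w = _csv.writer(fh)
                w.writerow(_COLUMNS[table])
                w.writerows(self._rows(table))
            out[table] = path
        return out


# ---------------------------------------------------------------------------
# At-rest encryption for backup containers (stdlib construction; see module
# docstring for the caveat).

_MAGIC = b"POCL1\n"
_PBKDF2_ITERS = 200_000


def _keys(passphrase: str, salt: bytes) -> tuple[bytes, bytes]:
    master = hashlib.pbkdf2_hmac(
        "sha256", passphrase.encode("utf-8"), salt, _PBKDF2_ITERS
    )
    return (
        hashlib.sha256(master + b"enc").digest(),
        hashlib.sha256(master + b"mac").digest(),
    )


def _keystream(key: bytes, nonce: bytes, n: int) -> bytes:
    out = bytearray()
    counter = 0
    while len(out) < n:
        out.extend(hashlib.sha256(key + nonce + counter.to_bytes(8, "big")).digest())
        counter += 1
    return bytes(out[:n])


def encrypt_container(blob: bytes, passphrase: str) -> bytes:
    salt = os.urandom(16)
    nonce = os.urandom(16)
    enc_key, mac_key = _keys(passphrase, salt)
    ct = bytes(a ^ b for a, b in zip(blob, _keystream(enc_key, nonce, len(blob))))
    tag = _hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()
    return _MAGIC + salt + nonce + tag + ct


def decrypt_container(blob: bytes, passphrase: str) -> bytes:
    if not blob.startswith(_MAGIC):
        raise InputError("not an encrypted container")
    body = blob[len(_MAGIC):]
    salt, nonce, tag, ct = body[:16], body[16:32], body[32:64], body[64:]
    enc_key, mac_key = _keys(passphrase, salt)
    expect = _hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()
    if not _hmac.compare_digest(tag, expect):
        raise IntegrityError("wrong passphrase or corrupted container")
    return bytes(a ^ b for a, b in zip(ct, _keystream(enc_key, nonce, len(ct))))
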