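"""Clinic identifier validation and session/record key generation.

Patients carry identifiers from up to three clinic systems: HTC (HIV
testing & counselling), CTC (HIV care & treatment) and ANC (antenatal).
HTC numbers are self-verifying under the ISO 7064 MOD 97-10 convention
(the whole number taken modulo 97 must equal 1, which detects every
single-digit substitution); CTC and ANC identifiers follow fixed
formats, generalised minimally from the printed examples
(``##-##-####-######`` and ``serial/year/FACILITY``).

Every stored row is keyed by (machine name, session ID, record number):
the session ID is the local start time as the 14-digit string
YYYYMMDDHHMMSS, and the six-digit record number starts at 000001 and
increments with each search attempt within the session.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional

from .errors import IdFormatError, InputError, SessionError

__all__ = [
    "CLINICS",
    "ClinicID",
    "validate_htc_id",
    "validate_ctc_id",
    "validate_anc_id",
    "validate_clinic_id",
    "SessionKey",
    "Session",
    "SessionAllocator",
    "make_session_id",
    "parse_session_id",
]

CLINICS = ("CTC", "HTC", "ANC")

_CTC_RE = re.compile(r"^\d{2}-\d{2}-\d{4}-\d{6}$")
_ANC_RE = re.compile(r"^(\d{4})/(\d{4})/([A-Z]+)$")
_ANC_YEAR_RANGE = (1990, 2099)


def _strip_ws(value: str) -> str:
    # field-printed IDs sometimes carry stray spaces around hyphens
    return "".join(value.split())


def validate_htc_id(value: str) -> bool:
    """True iff ``value`` is a digit string whose integer value satisfies
    N mod 97 == 1 (ISO 7064 MOD 97-10).

    Non-digit input raises :class:`IdFormatError` — a malformed entry is
    a different failure from a mistyped digit caught by the checksum.
    """
    value = _strip_ws(value)
    if not value or not value.isdigit():
        raise IdFormatError(f"HTC ID must be all digits, got {value!r}")
    return int(value) % 97 == 1


def validate_ctc_id(value: str) -> bool:
    """True iff ``value`` matches the CTC pattern ##-##-####-######."""
    return bool(_CTC_RE.match(_strip_ws(value)))


def validate_anc_id(value: str) -> bool:
    """True iff ``value`` matches serial/year/FACILITY with a plausible year."""
    m = _ANC_RE.match(_strip_ws(value).upper())
    if not m:
        return False
    year = int(m.group(2))
    return _ANC_YEAR_RANGE[0] <= year <= _ANC_YEAR_RANGE[1]


@dataclass(frozen=True)
class ClinicID:
    """One clinic identifier with its validation outcome."""

    clinic: str
    value: str
    valid: bool


def validate_clinic_id(clinic: str, value: str) -> ClinicID:
    clinic = clinic.upper()
    if clinic not in CLINICS:
        raise InputError(f"unknown clinic system {clinic!r}; expected one of {CLINICS}")
    value = _strip_ws(value)
    if clinic == "HTC":
        try:
            ok = validate_htc_id(value)
        except IdFormatError:
            ok = False
    elif clinic == "CTC":
        ok = validate_ctc_id(value)
    else:
        ok = validate_anc_id(value)
    return ClinicID(clinic=clinic, value=value, valid=ok)


# ---------------------------------------------------------------------------
# Session keys

_SESSION_FMT = "%Y%m%d%H%M%S"
_MAX_RECORD_NUMBER = 999_999


def make_session_id(timestamp: _dt.datetime) -> str:
    """14-digit local-time session ID, e.g. 2017-06-01 09:30:00 ->
    '20170601093000'."""
    return timestamp.strftime(_SESSION_FMT)


def parse_session_id(session_id: str) -> _dt.datetime:
    return _dt.datetime.strptime(session_id, _SESSION_FMT)


@dataclass(frozen=True)
class SessionKey:
    """Compound key stamped on every stored row."""

    machine_name: str
    session_id: str
    record_number: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.machine_name, self.session_id, self.record_number)


class Session:
    """One patient interaction on one machine: issues the record numbers
    for consecutive search attempts."""

    def __init__(self, machine_name: str, started_at: Optional[_dt.datetime] = None):
        if not machine_name:
            raise InputError("machine_name must be non-empty")
        self.machine_name = machine_name
        self.started_at = started_at or _dt.datetime.now()
        self.session_id = make_session_id(self.started_at)
        self._counter = 0

    def next_record_number(self) -> str:
        """Six-digit, zero-padded, starting '000001'; raises on overflow."""
        if self._counter >= _MAX_RECORD_NUMBER:
            raise SessionError("record number overflow (more than 999999 attempts)")
        self._counter += 1
        return f"{self._counter:06d}"

    def key(self, record_number: str) -> SessionKey:
        return SessionKey(self.machine_name, self.session_id, record_number)


class SessionAllocator:
    """Starts sessions on one machine guaranteeing distinct session IDs.

    Two sessions started within the same clock second would collide on
    (machine, session_id); the allocator bumps the later one to the next
    free second, so keys never collide.
    """

    def __init__(self, machine_name: str):
        self.machine_name = machine_name
        self._last: Optional[_dt.datetime] = None

    def observe(self, started_at: _dt.datetime) -> None:
        """Register a session start seen elsewhere (e.g. already persisted
        in a store) so newly issued IDs never collide with it."""
        started_at = started_at.replace(microsecond=0)
        if self._last is None or started_at > self._last:
            self._last = started_at

    def start(self, now: Optional[_dt.datetime] = None) -> Session:
        now = (now or _dt.datetime.now()).replace(microsecond=0)
        if self._last is not None and now <= self._last:
            now = self._last + _dt.timedelta(seconds=1)
        self._last = now
        return Session(self.machine_name, started_at=now)
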