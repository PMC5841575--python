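"""Synthetic registries, households and corrupted patient queries.

No real surveillance data can be shipped, so every other module is
exercised against generated data that mimics the structure of a rural
HDSS extract: households of 1–8 co-resident members grouped under shared
ten-cell leaders (one TCL per block of ~10 households), a minority of
identities holding two or three residency-episode records under distinct
record IDs, and partial dates of birth.

Queries are derived from a chosen source record and then perturbed the
way field-reported identifiers differ from registry spellings: single
character typos (substitution, transposition, deletion), switched name
order, a maiden-name substitution emulating marriage, birth-year recall
jitter, and missing fields.  Each corrupted query is returned with the
true record ID so rank-recovery can be measured.

Everything is deterministic under a seed.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field as _dcfield
from typing import Optional

from .registry import OUTSIDE_AREA, Registry, RegistryRecord, SearchQuery

__all__ = [
    "CorruptionConfig",
    "generate_registry",
    "corrupt_query",
    "generate_cohort",
    "table1_fixture",
    "FIRST_NAMES",
    "SURNAMES",
]

# Invented Tanzanian-plausible token pools; includes the tokens used by the
# packaged worked cases so those can be replayed against generated decoys.
FIRST_NAMES = [
    "PETER", "PASTORY", "SUZANNE", "LUZALIE", "JOSEPHI", "KOYA", "DOTTO",
    "HELENA", "MICHAEL", "MIZIMALLI", "MABINA", "MARIA", "ESTHER", "NEEMA",
    "BARAKA", "EMMANUEL", "JUMA", "AMINA", "FATUMA", "ZAWADI", "REHEMA",
    "GODFREY", "WILSON", "AGNES", "PENDO", "UPENDO", "SALOME", "DEBORA",
    "YOHANA", "PAULO", "SIMON", "ANNA", "GRACE", "IRENE", "LUCIA",
]
SURNAMES = [
    "JAKKU", "SWAKALA", "TIMOS", "LENARD", "WILLIAMS", "JONAS", "ZABRON",
    "MATHIAS", "BONIFASI", "SAHANNI", "SALU", "MSHIMO", "MALIGANYA",
    "NDALAHAWA", "PALO", "MAKOYE", "KASHINJE", "MASANJA", "NGOLLO",
    "BUNDALA", "SHIJA", "KULWA", "MAGESA", "NKAMBA", "LUBINZA", "SAYI",
    "GINYEBU", "MIHAMBO", "NYANDA", "MALALE", "BUJIKU", "LIMBU",
]
VILLAGES = {
    "KISESA": ["KISESA KATI", "ILENDEJA", "KITUMBA"],
    "KANYAMA": ["CHANGABE", "NYAN'HELELA", "MWABALUHI"],
    "IHAYABUYAGA": ["ILENDEJA", "NG'WANG'HALANGA"],
    "WELAMASONGA": ["BUGANDO", "MWABAGALU"],
    "BUKANDWE": ["NYASHIMBA", "MIGATA"],
}

_HOUSEHOLD_SIZES = (1, 2, 3, 4, 5, 6, 7, 8)
_HOUSEHOLDS_PER_TCL = 10


@dataclass(frozen=True)
class CorruptionConfig:
    """Rates of the perturbations applied when deriving a query from its
    source record.  All probabilities in [0, 1]; fully deterministic
    given ``seed``.

    ``typo_rate`` applies per name token; ``birth_year_jitter`` is the
    maximum recall error in years (the jitter is drawn uniformly from
    [-magnitude, +magnitude] with probability ``birth_year_jitter_rate``).
    Missingness rates emulate fields a patient does not report.
    """

    typo_rate: float = 0.3
    name_order_swap: float = 0.1
    maiden_substitution: float = 0.05
    birth_year_jitter: int = 1
    birth_year_jitter_rate: float = 0.3
    missing_birth_month: float = 0.5
    missing_birth_day: float = 0.6
    missing_subvillage: float = 0.2
    missing_hh_member: float = 0.2
    missing_tcl: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self):
        for name in (
            "typo_rate", "name_order_swap", "maiden_substitution",
            "birth_year_jitter_rate", "missing_birth_month",
            "missing_birth_day", "missing_subvillage",
            "missing_hh_member", "missing_tcl",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


def _record_id(rng: random.Random, used: set) -> str:
    while True:
        rid = f"{rng.randrange(10**10, 10**11)}"
        if rid not in used:
            used.add(rid)
            return rid


def generate_registry(
    n: int = 100,
    seed: Optional[int] = None,
    multi_episode_fraction: float = 0.1,
    extract_date: Optional[_dt.date] = None,
) -> Registry:
    """Generate ``n`` registry records (default 100, the size of the
    packaged worked example).

    Identities are placed in households of 1–8 members; households are
    grouped in blocks of ~10 sharing one ten-cell leader.  A fraction of
    identities (default 10%) hold 2–3 residency-episode records with
    distinct record IDs but consistent personal details — the duplicate
    structure interactive review must cope with.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    used_ids: set = set()
    records: list[RegistryRecord] = []
    hh_counter = 0
    tcl_pool: list[tuple[str, ...]] = []

    def new_tcl() -> tuple[str, ...]:
        return (rng.choice(FIRST_NAMES), rng.choice(SURNAMES))

    while len(records) < n:
        if hh_counter % _HOUSEHOLDS_PER_TCL == 0:
            tcl_pool.append(new_tcl())
        tcl = tcl_pool[-1]
        hh_counter += 1
        household_id = f"H{hh_counter:05d}"
        village = rng.choice(sorted(VILLAGES))
        subvillage = rng.choice(VILLAGES[village])
        size = rng.choice(_HOUSEHOLD_SIZES)
        for _ in range(size):
            if len(records) >= n:
                break
            sex = rng.choice("MF")
            birth_year = rng.randint(1940, 2015)
            names = [rng.choice(FIRST_NAMES), rng.choice(SURNAMES)]
            if rng.random() < 0.5:
                names.append(rng.choice(SURNAMES))
            start = rng.randint(max(birth_year, 1994), 2016)
            end = None if rng.random() < 0.4 else rng.randint(start, 2017)
            base = dict(
                names=tuple(names),
                sex=sex,
                birth_year=birth_year,
                birth_month=rng.randint(1, 12) if rng.random() < 0.6 else None,
                birth_day=rng.randint(1, 28) if rng.random() < 0.4 else None,
                village=village,
                subvillage=subvillage if rng.random() < 0.9 else None,
                household_id=household_id,
                tcl_names=tcl,
            )
            records.append(
                RegistryRecord(
                    record_id=_record_id(rng, used_ids),
                    residency_start_year=start,
                    residency_end_year=end,
                    **base,
                )
            )
            # multi-episode identities: extra records in other households,
            # earlier episodes, same person
            if rng.random() < multi_episode_fraction:
                extra = rng.randint(1, 2)
                prev_start = start
                for _ in range(extra):
                    if len(records) >= n:
                        break
                    gap = rng.randint(1, 4)
                    e_end = prev_start - gap
                    e_start = max(birth_year, e_end - rng.randint(1, 10))
                    if e_start > e_end:
                        continue
                    hh_counter += 1
                    other_village = rng.choice(sorted(VILLAGES))
                    ep = dict(base)
                    ep["village"] = other_village
                    ep["subvillage"] = rng.choice(VILLAGES[other_village])
                    ep["household_id"] = f"H{hh_counter:05d}"
                    records.append(
                        RegistryRecord(
                            record_id=_record_id(rng, used_ids),
                            residency_start_year=e_start,
                            residency_end_year=e_end,
                            **ep,
                        )
                    )
                    prev_start = e_start
    return Registry(records[:n], extract_date=extract_date or _dt.date(2017, 1, 1))


_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _typo(token: str, rng: random.Random) -> str:
    """One character edit: substitution, adjacent transposition or deletion."""
    if len(token) < 2:
        return rng.choice(_ALPHABET.replace(token or "A", "", 1) or "B")
    kind = rng.choice(["sub", "trans", "del"])
    i = rng.randrange(len(token))
    if kind == "sub":
        repl = rng.choice([c for c in _ALPHABET if c != token[i]])
        return token[:i] + repl + token[i + 1:]
    if kind == "trans":
        i = rng.randrange(len(token) - 1)
        if token[i] == token[i + 1]:  # no-op swap would leave the name intact
            repl = rng.choice([c for c in _ALPHABET if c != token[i]])
            return token[:i] + repl + token[i + 1:]
        return token[:i] + token[i + 1] + token[i] + token[i + 2:]
    return token[:i] + token[i + 1:]


def corrupt_query(
    record: RegistryRecord,
    registry: Registry,
    config: Optional[CorruptionConfig] = None,
    rng: Optional[random.Random] = None,
) -> tuple[SearchQuery, str]:
    """Derive a patient-reported query from ``record`` with seeded
    perturbations; returns ``(query, true_record_id)``.

    With all rates zero the query reproduces the record's fields (plus a
    co-resident's names, when the household has one).
    """
    if record.record_id not in registry:
        raise ValueError("record must belong to the registry")
    config = config or CorruptionConfig()
    rng = rng or random.Random(config.seed)

    names = list(record.names)
    if rng.random() < config.maiden_substitution and len(names) >= 2:
        names[-1] = rng.choice([s for s in SURNAMES if s != names[-1]])
    names = [
        _typo(tok, rng) if rng.random() < config.typo_rate else tok for tok in names
    ]
    if len(names) >= 2 and rng.random() < config.name_order_swap:
        i, j = rng.sample(range(len(names)), 2)
        names[i], names[j] = names[j], names[i]

    birth_year = record.birth_year
    if birth_year is not None and rng.random() < config.birth_year_jitter_rate:
        birth_year += rng.randint(-config.birth_year_jitter, config.birth_year_jitter)

    birth_month = record.birth_month
    if rng.random() < config.missing_birth_month:
        birth_month = None
    birth_day = record.birth_day
    if rng.random() < config.missing_birth_day:
        birth_day = None
    subvillage = record.subvillage
    if rng.random() < config.missing_subvillage:
        subvillage = None

    conames = registry.household_conames(record.record_id)
    hh_member: tuple[str, ...] = ()
    if conames and rng.random() >= config.missing_hh_member:
        # the patient reports one co-resident by up to three names
        members = registry.household_members(record.record_id)
        others = [m for m in members if m != record.names]
        if others:
            hh_member = rng.choice(others)[:3]
    tcl = record.tcl_names
    if rng.random() < config.missing_tcl:
        tcl = ()

    query = SearchQuery(
        names=tuple(names),
        sex=record.sex,
        birth_year=birth_year,
        birth_month=birth_month,
        birth_day=birth_day,
        village=record.village,
        subvillage=subvillage,
        residency_start_year=record.residency_start_year,
        residency_end_year=record.residency_end_year,
        hh_member_names=hh_member,
        tcl_names=tcl,
    )
    return query, record.record_id


def generate_cohort(
    registry: Registry,
    k: int,
    config: Optional[CorruptionConfig] = None,
    recent_resident_fraction: float = 0.25,
    seed: Optional[int] = None,
) -> list[tuple[SearchQuery, Optional[str]]]:
    """Sample ``k`` (query, truth) pairs with replacement from the registry.

    A configurable fraction (default 25%, roughly the share of clinic
    attendees who settled after the last census round in this setting)
    are *recent residents*: invented people with no true record, whose
    truth is ``None`` and whose ``first_residence_date`` postdates the
    registry extract.
    """
    if len(registry) == 0:
        raise ValueError("registry must be non-empty")
    if not 0.0 <= recent_resident_fraction <= 1.0:
        raise ValueError("recent_resident_fraction outside [0, 1]")
    config = config or CorruptionConfig()
    rng = random.Random(seed if seed is not None else config.seed)
    n_recent = round(k * recent_resident_fraction)
    extract = registry.extract_date or _dt.date(2017, 1, 1)
    out: list[tuple[SearchQuery, Optional[str]]] = []
    for _ in range(k - n_recent):
        record = rng.choice(registry.records)
        out.append(corrupt_query(record, registry, config, rng))
    for _ in range(n_recent):
        village = rng.choice(sorted(VILLAGES))
        query = SearchQuery(
            names=(rng.choice(FIRST_NAMES), rng.choice(SURNAMES)),
            sex=rng.choice("MF"),
            birth_year=rng.randint(1950, 2005),
            village=village,
            subvillage=rng.choice(VILLAGES[village]),
            first_residence_date=extract + _dt.timedelta(days=rng.randint(1, 300)),
        )
        out.append((query, None))
    rng.shuffle(out)
    return out


def table1_fixture() -> tuple[Registry, dict]:
    """Synthetic stand-in reproducing the three packaged worked cases.

    The original supplementary fake dataset is not redistributable, so
    this fixture reconstructs its three documented cases from the printed
    identifiers: the true records carry the printed HDSS IDs, minor
    spelling differences from the reported names, Case 2's switched name
    order and Case 3's maiden-name episode, all embedded in 100 records
    of generated decoys.

    Returns ``(registry, cases)`` where ``cases`` maps case keys to dicts
    with the reported query, clinic IDs and true record ID (case 3 has
    two searches; its second episode is outside the area, unsearchable).
    """
    base = generate_registry(n=96, seed=20170601)
    decoys = [r for r in base]
    truth_records = [
        # Case 1: reported PETER JAKKU -> registry spelling differs slightly
        RegistryRecord(
            record_id="22341597005",
            names=("PETA", "JAKU"),
            sex="M", birth_year=2004, birth_month=8, birth_day=15,
            village="KANYAMA", subvillage="CHANGABE",
            residency_start_year=2012, residency_end_year=2014,
            household_id="HC0001", tcl_names=("HELENA", "MSHIMO"),
        ),
        RegistryRecord(  # case 1 co-resident
            record_id="22341597006",
            names=("LUZALIE", "MATHIAS"),
            sex="F", birth_year=1979,
            birth_month=None, birth_day=None,
            village="KANYAMA", subvillage="CHANGABE",
            residency_start_year=2010, residency_end_year=None,
            household_id="HC0001", tcl_names=("HELENA", "MSHIMO"),
        ),
        # Case 2: names switched in order on the registry record
        RegistryRecord(
            record_id="77537712004",
            names=("SWAKARA", "PASTORY", "TIMOS"),
            sex="F", birth_year=1984, birth_month=9, birth_day=None,
            village="KANYAMA", subvillage="NYAN'HELELA",
            residency_start_year=2011, residency_end_year=2014,
            household_id="HC0002", tcl_names=("MICHAEL", "MALIGANYA"),
        ),
        RegistryRecord(  # case 2 co-resident
            record_id="77537712005",
            names=("JOSEPHI", "BONIFASI"),
            sex="M", birth_year=1980,
            birth_month=None, birth_day=None,
            village="KANYAMA", subvillage="NYAN'HELELA",
            residency_start_year=2011, residency_end_year=None,
            household_id="HC0002", tcl_names=("MICHAEL", "MALIGANYA"),
        ),
        # Case 3 episode 1 (maiden name, found on the second search)
        RegistryRecord(
            record_id="10012368001",
            names=("SUZANE", "LENARD", "WILIAMS"),
            sex="F", birth_year=1981, birth_month=None, birth_day=None,
            village="KISESA", subvillage="KISESA KATI",
            residency_start_year=1995, residency_end_year=2003,
            household_id="HC0003", tcl_names=("MIZIMALLI", "NDALAHAWA"),
        ),
        RegistryRecord(  # case 3 episode-1 co-resident
            record_id="10012368002",
            names=("KOYA", "SAHANNI"),
            sex="M", birth_year=1955,
            birth_month=None, birth_day=None,
            village="KISESA", subvillage="KISESA KATI",
            residency_start_year=1995, residency_end_year=None,
            household_id="HC0003", tcl_names=("MIZIMALLI", "NDALAHAWA"),
        ),
        # Case 3 episode 3 (married name)
        RegistryRecord(
            record_id="10025490004",
            names=("SUZANE", "JONAS", "ZABRON"),
            sex="F", birth_year=1981, birth_month=None, birth_day=None,
            village="IHAYABUYAGA", subvillage="ILENDEJA",
            residency_start_year=2006, residency_end_year=2014,
            household_id="HC0004", tcl_names=("MABINA", "PALO"),
        ),
        RegistryRecord(  # case 3 episode-3 co-resident
            record_id="10025490005",
            names=("DOTTO", "SALU"),
            sex="M", birth_year=1978,
            birth_month=None, birth_day=None,
            village="IHAYABUYAGA", subvillage="ILENDEJA",
            residency_start_year=2006, residency_end_year=None,
            household_id="HC0004", tcl_names=("MABINA", "PALO"),
        ),
    ]
    registry = Registry(
        decoys[: 100 - len(truth_records)] + truth_records,
        extract_date=_dt.date(2017, 1, 1),
    )
    cases = {
        "case1": {
            "clinic_ids": [("CTC", "77-10-4545-253004")],
            "query": SearchQuery(
                names=("PETER", "JAKKU"), sex="M",
                birth_year=2004, birth_month=8, birth_day=15,
                village="KANYAMA", subvillage="CHANGABE",
                residency_start_year=2012, residency_end_year=2014,
                hh_member_names=("LUZALIE", "MATHIAS"),
                tcl_names=("HELENA", "MSHIMO"),
            ),
            "true_record_id": "22341597005",
            "note": "All reported residency episodes found.",
        },
        "case2": {
            "clinic_ids": [("ANC", "1234/2017/KISESA"), ("HTC", "44447050")],
            "query": SearchQuery(
                names=("PASTORY", "SWAKALA", "TIMOS"), sex="F",
                birth_year=1984, birth_month=9,
                village="KANYAMA", subvillage="NYAN'HELELA",
                residency_start_year=2010, residency_end_year=2014,
                hh_member_names=("JOSEPHI", "BONIFASI"),
                tcl_names=("MICHAEL", "MALIGANYA"),
            ),
            "true_record_id": "77537712004",
            "note": "All reported residency episodes found.",
        },
        "case3": {
            "clinic_ids": [("HTC", "44618061")],
            "query": SearchQuery(  # first search: maiden-name episode
                names=("SUZANNE", "LENARD", "WILLIAMS"), sex="F",
                birth_year=1980,
                village="KISESA", subvillage="KISESA KATI",
                residency_start_year=1995, residency_end_year=2003,
                hh_member_names=("KOYA", "SAHANNI"),
                tcl_names=("MIZIMALLI", "NDALAHAWA"),
            ),
            "query_outside": SearchQuery(  # second episode: unsearchable
                names=("SUZANNE", "JONAS", "ZABRON"), sex="F",
                birth_year=1980, village=OUTSIDE_AREA,
                residency_start_year=2003, residency_end_year=2006,
            ),
            "query2": SearchQuery(  # third episode, married name
                names=("SUZANNE", "JONAS", "ZABRON"), sex="F",
                birth_year=1980,
                village="IHAYABUYAGA", subvillage="ILENDEJA",
                residency_start_year=2006, residency_end_year=2014,
                hh_member_names=("DOTTO", "SALU"),
                tcl_names=("MABINA", "PALO"),
            ),
            "true_record_id": "10012368001",
            "true_record_id_2": "10025490004",
            "note": "All reported residency episodes found.",
        },
    }
    return registry, cases
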