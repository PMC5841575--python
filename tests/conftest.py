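import datetime as dt

import pytest

import poclink as p


@pytest.fixture(scope="session")
def registry30():
    """Small synthetic registry for exhaustive-oracle tests."""
    return p.generate_registry(n=30, seed=11)


@pytest.fixture(scope="session")
def registry100():
    return p.generate_registry(n=100, seed=5)


@pytest.fixture(scope="session")
def params():
    return p.MatchParameters.default()


@pytest.fixture(scope="session")
def worked_cases():
    """Packaged synthetic stand-in for the three documented worked cases."""
    return p.table1_fixture()


@pytest.fixture()
def store():
    return p.SessionStore(":memory:", extract_date=dt.date(2017, 1, 1))


@pytest.fixture()
def session():
    return p.Session("machine1", started_at=dt.datetime(2017, 6, 1, 9, 30, 0))


def make_query(record, registry, **overrides):
    """Uncorrupted query copying a record's fields (plus one co-resident)."""
    members = registry.household_members(record.record_id)
    others = [m for m in members if m != record.names]
    base = dict(
        names=record.names,
        sex=record.sex,
        birth_year=record.birth_year,
        birth_month=record.birth_month,
        birth_day=record.birth_day,
        village=record.village,
        subvillage=record.subvillage,
        residency_start_year=record.residency_start_year,
        residency_end_year=record.residency_end_year,
        hh_member_names=others[0][:3] if others else (),
        tcl_names=record.tcl_names,
    )
    base.update(overrides)
    return p.SearchQuery(**base)
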