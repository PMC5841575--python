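"""Session store: four tables, clinic-ID lookup, backup merge, encryption."""

import datetime as dt
import random

import pytest

import poclink as p

CTC = ("CTC", "77-10-4545-253004")
HTC = ("HTC", "44618061")
ANC = ("ANC", "1234/2017/KISESA")


def _query(**kw):
    base = dict(names=("PETER", "JAKKU"), sex="M", birth_year=1980, village="KISESA")
    base.update(kw)
    return p.SearchQuery(**base)


def _candidate(record_id="22341597005", score=25.0, rank=1):
    return p.CandidateMatch(
        record_id=record_id, score=score, rank=rank,
        field_weights={}, warnings=(), name_score_total=2.0,
    )


def test_two_attempts_share_session_and_iterate(store, session):
    k1 = store.record_search_attempt(session, _query(), [CTC])
    k2 = store.record_search_attempt(session, _query(), [CTC])
    assert k1.session_id == k2.session_id == "20170601093000"
    assert (k1.record_number, k2.record_number) == ("000001", "000002")
    assert store.row_counts()["registry_rows"] == 2


def test_invalid_clinic_id_rejected_before_write(store, session):
    with pytest.raises(p.InputError):
        store.record_search_attempt(session, _query(), [("HTC", "44618062")])
    with pytest.raises(p.InputError):
        store.record_search_attempt(session, _query(), [])
    assert store.row_counts()["registry_rows"] == 0


def test_rows_retrievable_by_any_entered_clinic_id(store, session):
    store.record_search_attempt(session, _query(), [ANC, HTC])
    for _, value in (ANC, HTC):
        assert store.lookup_by_clinic_id(value).status == "Not matched"


def test_save_match_note_visit_roundtrip(store, session):
    key = store.record_search_attempt(session, _query(), [CTC])
    store.save_match(key, _candidate())
    store.save_note(key, "All reported residency episodes found.")
    store.log_visit(key, dt.date(2017, 6, 1))
    summary = store.lookup_by_clinic_id(CTC[1])
    assert summary.status == "Matched"
    assert summary.matches[0]["hdss_record_id"] == "22341597005"
    assert summary.matches[0]["rank"] == 1
    assert summary.notes == ("All reported residency episodes found.",)
    assert summary.visit_dates == ("2017-06-01",)


def test_unknown_key_is_referential_error(store, session):
    bad = p.SessionKey("machine1", "20170601093000", "000042")
    with pytest.raises(p.LookupError_):
        store.save_match(bad, _candidate())
    with pytest.raises(p.LookupError_):
        store.save_note(bad, "x")


def test_note_and_visit_input_validation(store, session):
    key = store.record_search_attempt(session, _query(), [CTC])
    with pytest.raises(p.InputError):
        store.save_note(key, "   ")
    with pytest.raises(p.InputError):
        store.log_visit(key, "2017-06-01")  # not a date object


def test_never_seen_id_is_new(store):
    summary = store.lookup_by_clinic_id("99999999")
    assert summary.status == "New"
    assert summary.notes == ()


def test_notes_most_recent_first(store, session):
    key = store.record_search_attempt(session, _query(), [CTC])
    store.save_note(key, "first", now=dt.datetime(2017, 6, 1, 9, 0))
    store.save_note(key, "second", now=dt.datetime(2017, 6, 2, 9, 0))
    assert store.lookup_by_clinic_id(CTC[1]).notes == ("second", "first")


def test_cross_clinic_transitive_linkage(store):
    """A session recording ANC+HTC ties both IDs to one patient; a later
    session adding CTC to the HTC joins the cluster too."""
    alloc = p.SessionAllocator("machine1")
    s1 = alloc.start(now=dt.datetime(2017, 6, 1, 9, 30))
    k1 = store.record_search_attempt(s1, _query(), [ANC, HTC])
    store.save_match(k1, _candidate())
    s2 = alloc.start(now=dt.datetime(2017, 6, 8, 10, 0))
    store.record_search_attempt(s2, _query(), [HTC, CTC])
    for _, value in (ANC, HTC, CTC):
        assert store.lookup_by_clinic_id(value).status == "Matched"


def test_recent_resident_flag(store, session):
    q = _query(first_residence_date=dt.date(2017, 5, 1))  # extract 2017-01-01
    store.record_search_attempt(session, q, [CTC])
    rows = store._rows("registry_rows")
    assert rows[0][6] == 1
    old = _query(first_residence_date=dt.date(2016, 5, 1))
    store.record_search_attempt(session, old, [CTC])
    assert store._rows("registry_rows")[1][6] == 0


def test_referential_integrity_clean(store, session):
    key = store.record_search_attempt(session, _query(), [CTC])
    store.save_match(key, _candidate())
    assert store.check_referential_integrity() == []


# -- backup / merge ------------------------------------------------------------


def _populate(machine, n_sessions, seed):
    rng = random.Random(seed)
    store = p.SessionStore(":memory:", extract_date=dt.date(2017, 1, 1))
    alloc = p.SessionAllocator(machine)
    t0 = dt.datetime(2017, 6, 1, 8, 0, 0)
    for i in range(n_sessions):
        session = alloc.start(now=t0 + dt.timedelta(minutes=i))
        key = store.record_search_attempt(
            session, _query(birth_year=rng.randint(1950, 2000)), [CTC],
            now=t0 + dt.timedelta(minutes=i),
        )
        if rng.random() < 0.7:
            store.save_match(key, _candidate(record_id=str(rng.randint(1, 50))),
                             now=t0 + dt.timedelta(minutes=i))
        if rng.random() < 0.5:
            store.save_note(key, f"note {i}", now=t0 + dt.timedelta(minutes=i))
        store.log_visit(key, dt.date(2017, 6, 1), now=t0 + dt.timedelta(minutes=i))
    return store


def _all_rows(store):
    return {t: store._rows(t) for t in ("registry_rows", "matches", "notes", "visits")}


def test_merge_commutative_and_idempotent(tmp_path):
    a = _populate("machineA", 6, seed=1)
    b = _populate("machineB", 4, seed=2)
    pa, pb = tmp_path / "a.json", tmp_path / "b.json"
    a.export_backup(pa)
    b.export_backup(pb)

    ab = p.SessionStore(":memory:")
    ab.import_merge(pa, pb)
    ba = p.SessionStore(":memory:")
    ba.import_merge(pb, pa)
    assert _all_rows(ab) == _all_rows(ba)

    aa = p.SessionStore(":memory:")
    aa.import_merge(pa, pa)
    assert _all_rows(aa) == _all_rows(a)


def test_merge_disjoint_counts_add(tmp_path):
    a = _populate("machineA", 5, seed=3)
    b = _populate("machineB", 7, seed=4)
    pa, pb = tmp_path / "a.json", tmp_path / "b.json"
    a.export_backup(pa)
    b.export_backup(pb)
    merged = p.SessionStore(":memory:")
    merged.import_merge(pa, pb)
    for t, n in merged.row_counts().items():
        assert n == a.row_counts()[t] + b.row_counts()[t]


def test_merge_conflict_newest_wins(tmp_path, session):
    s1 = p.SessionStore(":memory:", extract_date=dt.date(2017, 1, 1))
    key = s1.record_search_attempt(session, _query(), [CTC])
    s1.save_match(key, _candidate(score=10.0), now=dt.datetime(2017, 6, 1, 9, 0))
    p1 = tmp_path / "old.json"
    s1.export_backup(p1)
    s1.save_match(key, _candidate(score=99.0), now=dt.datetime(2017, 6, 2, 9, 0))
    p2 = tmp_path / "new.json"
    s1.export_backup(p2)

    merged = p.SessionStore(":memory:")
    conflicts = merged.import_merge(p1, p2)
    assert len(conflicts) == 1
    (row,) = merged._rows("matches")
    assert row[4] == 99.0


def test_persistence_roundtrip(tmp_path, session):
    store = _populate("machineA", 5, seed=5)
    path = tmp_path / "backup.json"
    store.export_backup(path)
    fresh = p.SessionStore(":memory:")
    fresh.import_merge(path)
    assert _all_rows(fresh) == _all_rows(store)


def test_encrypted_backup_roundtrip(tmp_path):
    store = _populate("machineA", 3, seed=6)
    path = tmp_path / "backup.enc"
    store.export_backup(path, passphrase="hunter2")
    fresh = p.SessionStore(":memory:")
    fresh.import_merge(path, passphrase="hunter2")
    assert _all_rows(fresh) == _all_rows(store)
    with pytest.raises(p.IntegrityError):
        p.SessionStore(":memory:").import_merge(path, passphrase="wrong")


def test_container_encryption_is_reversible():
    blob = b'{"registry_rows": []}'
    enc = p.encrypt_container(blob, "pass")
    assert enc != blob
    assert p.decrypt_container(enc, "pass") == blob
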