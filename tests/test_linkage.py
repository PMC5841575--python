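"""Linkage engine: agreement rules, weights, ranking, warnings, u-estimates."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poclink as p
from poclink.linkage import Agreement, _weights  # noqa: F401

from conftest import make_query


# -- agreement rules ---------------------------------------------------------

def test_birth_year_tolerance(registry30, params):
    rec = registry30.records[0]
    base = make_query(rec, registry30)
    for dy, expect in [(0, Agreement.AGREE), (2, Agreement.AGREE),
                       (3, Agreement.DISAGREE), (-2, Agreement.AGREE)]:
        q = make_query(rec, registry30, birth_year=rec.birth_year + dy)
        vec = p.evaluate_agreement(q, rec, params)
        assert vec.states["birth_year"] is expect, dy
    q = make_query(rec, registry30, birth_year=None)
    assert p.evaluate_agreement(q, rec, params).states["birth_year"] is Agreement.MISSING
    assert p.evaluate_agreement(base, rec, params).states["sex"] is Agreement.AGREE


def test_sex_requires_exact_match(registry30, params):
    rec = registry30.records[0]
    q = make_query(rec, registry30, sex="F" if rec.sex == "M" else "M")
    assert p.evaluate_agreement(q, rec, params).states["sex"] is Agreement.DISAGREE


def test_name_threshold_boundary(params):
    """A paired score of exactly 0.8 agrees; just below disagrees."""
    rec = p.RegistryRecord(
        record_id="1", names=("ABCDEF",), sex="M", birth_year=1980,
        birth_month=None, birth_day=None, village="V", subvillage=None,
        residency_start_year=2000, residency_end_year=None, household_id="H1",
    )
    # find tokens whose JW against ABCDEF straddles the threshold
    hi = p.SearchQuery(names=("ABCDXX",), village="V")   # jw ~0.866
    lo = p.SearchQuery(names=("ABXXXX",), village="V")   # jw ~0.733
    assert p.jaro_winkler("ABCDXX", "ABCDEF") >= 0.8
    assert p.jaro_winkler("ABXXXX", "ABCDEF") < 0.8
    assert p.evaluate_agreement(hi, rec, params).states["name1"] is Agreement.AGREE
    assert p.evaluate_agreement(lo, rec, params).states["name1"] is Agreement.DISAGREE


def test_unpaired_names_are_missing(registry30, params):
    rec = registry30.records[0]
    q = make_query(rec, registry30, names=rec.names[:1])
    vec = p.evaluate_agreement(q, rec, params)
    assert vec.states["name1"] is Agreement.AGREE
    assert vec.states["name3"] is Agreement.MISSING


def test_unsearchable_query_refused(registry30, params):
    q = p.SearchQuery(names=("A",), village=p.OUTSIDE_AREA)
    with pytest.raises(p.UnsearchableQueryError):
        p.search(q, registry30, params)


# -- weights -----------------------------------------------------------------

@pytest.mark.parametrize(
    "m, u, state, expected",
    [
        (0.9, 0.1, Agreement.AGREE, math.log2(9)),
        (0.9, 0.1, Agreement.DISAGREE, math.log2(1 / 9)),
        (0.5, 0.5, Agreement.AGREE, 0.0),
        (0.5, 0.5, Agreement.DISAGREE, 0.0),
        (0.7, 0.2, Agreement.MISSING, 0.0),
    ],
)
def test_field_weight_frozen(m, u, state, expected):
    assert p.field_weight(m, u, state) == pytest.approx(expected, abs=1e-12)


def test_field_weight_rejects_bad_probabilities():
    for m, u in [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0), (-0.1, 0.5)]:
        with pytest.raises(p.ParameterError):
            p.field_weight(m, u, Agreement.AGREE)


@given(
    m=st.floats(0.01, 0.99), u=st.floats(0.01, 0.99),
    state=st.sampled_from([Agreement.AGREE, Agreement.DISAGREE, Agreement.MISSING]),
)
@settings(max_examples=200, deadline=None)
def test_field_weight_formula_grid(m, u, state):
    w = p.field_weight(m, u, state)
    if state is Agreement.AGREE:
        assert w == pytest.approx(math.log2(m / u), abs=1e-12)
    elif state is Agreement.DISAGREE:
        assert w == pytest.approx(math.log2((1 - m) / (1 - u)), abs=1e-12)
    else:
        assert w == 0.0


def test_match_score_is_sum_of_field_weights(registry30, params):
    """Oracle: independent re-summation of per-field weights."""
    rng = random.Random(3)
    for _ in range(20):
        rec = rng.choice(registry30.records)
        q, _ = p.corrupt_query(rec, registry30, p.CorruptionConfig(seed=rng.randrange(2**31)))
        conames = registry30.household_conames(rec.record_id)
        vec = p.evaluate_agreement(q, rec, params, conames)
        expected = sum(
            p.field_weight(params.m[f], params.u[f], vec.states[f]) for f in p.FIELDS
        )
        assert p.match_score(q, rec, params, conames) == pytest.approx(expected)


def test_all_missing_scores_zero(params):
    rec = p.RegistryRecord(
        record_id="1", names=("ZZZZZZ",), sex=None, birth_year=None,
        birth_month=None, birth_day=None, village="V", subvillage=None,
        residency_start_year=2000, residency_end_year=None, household_id="H1",
    )
    # single query name pairs against the record name, so only name1 is
    # non-missing; remove its contribution by checking the other fields
    q = p.SearchQuery(names=("AAAAAA",))
    vec = p.evaluate_agreement(q, rec, params)
    others = [f for f in p.FIELDS if f != "name1"]
    assert all(vec.states[f] is Agreement.MISSING for f in others)
    assert sum(
        p.field_weight(params.m[f], params.u[f], vec.states[f]) for f in others
    ) == 0.0


def test_agreeing_informative_field_strictly_increases_score(registry30):
    """Adding an AGREE field with m>u raises the score; m=u leaves it flat."""
    rec = registry30.records[0]
    q_with = make_query(rec, registry30)
    q_without = make_query(rec, registry30, sex=None)
    params = p.MatchParameters.default()
    conames = registry30.household_conames(rec.record_id)
    s_with = p.match_score(q_with, rec, params, conames)
    s_without = p.match_score(q_without, rec, params, conames)
    assert s_with > s_without
    flat = p.MatchParameters(
        m={**params.m, "sex": 0.5}, u={**params.u, "sex": 0.5}
    )
    assert p.match_score(q_with, rec, flat, conames) == pytest.approx(
        p.match_score(q_without, rec, flat, conames)
    )


# -- search / ranking ----------------------------------------------------------

def test_search_returns_top_20_of_100(registry100, params):
    q = make_query(registry100.records[0], registry100)
    result = p.search(q, registry100, params)
    assert len(result) == 20
    assert [c.rank for c in result] == list(range(1, 21))
    scores = [c.score for c in result]
    assert scores == sorted(scores, reverse=True)


def test_search_small_registry_returns_all(registry30, params):
    small = p.Registry(registry30.records[:5])
    q = make_query(registry30.records[0], registry30)
    assert len(p.search(q, small, params)) == 5


def test_search_equals_brute_force_sort(registry30, params):
    """Oracle: full score table, sorted by (-score, record_id)."""
    rng = random.Random(9)
    for _ in range(10):
        rec = rng.choice(registry30.records)
        q, _ = p.corrupt_query(
            rec, registry30, p.CorruptionConfig(seed=rng.randrange(2**31))
        )
        table = [
            (
                -p.match_score(
                    q.normalized(), r, params, registry30.household_conames(r.record_id)
                ),
                r.record_id,
            )
            for r in registry30
        ]
        table.sort()
        expected = [rid for _, rid in table][: params.top_k]
        got = [c.record_id for c in p.search(q, registry30, params)]
        assert got == expected


def test_own_record_scores_highest(registry30, params):
    """An uncorrupted query prefers its source record over any other."""
    for rec in list(registry30)[:10]:
        q = make_query(rec, registry30)
        scores = {
            r.record_id: p.match_score(
                q, r, params, registry30.household_conames(r.record_id)
            )
            for r in registry30
        }
        best = max(scores.values())
        assert scores[rec.record_id] == pytest.approx(best)


def test_score_invariant_to_name_order(registry30, params):
    rec = next(r for r in registry30 if len(r.names) >= 2)
    q1 = make_query(rec, registry30)
    q2 = make_query(rec, registry30, names=tuple(reversed(rec.names)))
    conames = registry30.household_conames(rec.record_id)
    assert p.match_score(q1, rec, params, conames) == pytest.approx(
        p.match_score(q2, rec, params, conames)
    )


# -- warnings ------------------------------------------------------------------

def _rec(**kw):
    base = dict(
        record_id="1", names=("PETER", "JAKKU"), sex="M", birth_year=1980,
        birth_month=None, birth_day=None, village="V", subvillage=None,
        residency_start_year=2000, residency_end_year=None, household_id="H1",
    )
    base.update(kw)
    return p.RegistryRecord(**base)


def test_age_gap_warning_boundary():
    q = p.SearchQuery(names=("PETER", "JAKKU"), birth_year=1991, village="V")
    assert p.AGE_GAP in p.match_warnings(q, _rec())          # delta 11
    q10 = p.SearchQuery(names=("PETER", "JAKKU"), birth_year=1990, village="V")
    assert p.AGE_GAP not in p.match_warnings(q10, _rec())    # delta 10 passes


def test_low_name_score_boundary_inclusive():
    # identical single name: total exactly 1.0 <= 1.6 -> warn
    q = p.SearchQuery(names=("PETER",), birth_year=1980)
    assert p.LOW_NAME_SCORE in p.match_warnings(q, _rec())
    # two identical names: total 2.0 -> no warning
    q2 = p.SearchQuery(names=("PETER", "JAKKU"), birth_year=1980)
    assert p.match_warnings(q2, _rec()) == []


def test_warning_total_exactly_1_6():
    # construct a pair summing to <= 1.6: one exact name + one dissimilar
    rec = _rec(names=("PETER", "QQQQQQ"))
    q = p.SearchQuery(names=("PETER", "ZZZXXX"), birth_year=1980)
    _, total = p.best_name_assignment(q.names, rec.names)
    assert total <= 1.6
    assert p.LOW_NAME_SCORE in p.match_warnings(q, rec)


# -- u estimation ----------------------------------------------------------------

def test_estimate_u_sex_balanced():
    rng = random.Random(0)
    recs = [
        _rec(record_id=str(i), sex="M" if i % 2 else "F", household_id=f"H{i}",
             names=(rng.choice(["AAA", "BBB", "CCC"]),))
        for i in range(1000)
    ]
    reg = p.Registry(recs)
    assert p.estimate_u(reg, "sex") == pytest.approx(0.5, abs=0.01)


def test_estimate_u_constant_field_clamped():
    recs = [_rec(record_id=str(i), sex="M", household_id=f"H{i}") for i in range(10)]
    reg = p.Registry(recs)
    assert p.estimate_u(reg, "sex") == pytest.approx(1.0, abs=1e-5)
    assert p.estimate_u(reg, "sex") < 1.0


def test_estimate_u_degenerate_field_errors():
    recs = [_rec(record_id=str(i), sex=None, household_id=f"H{i}") for i in range(5)]
    reg = p.Registry(recs)
    with pytest.raises(p.EstimationError):
        p.estimate_u(reg, "sex")


@pytest.mark.parametrize("field", ["sex", "village", "birth_year", "name1"])
def test_estimate_u_equals_exhaustive_pair_fraction(registry30, params, field):
    """Oracle: agreement fraction over all 435 record pairs."""
    vals = []
    for rec in registry30:
        if field == "name1":
            v = rec.names[0] if rec.names else None
        else:
            v = getattr(rec, field)
        if v is not None and v != "":
            vals.append(v)
    pairs = list(itertools.combinations(vals, 2))

    def agree(a, b):
        if field == "birth_year":
            return abs(a - b) <= params.yob_tolerance
        if field == "name1":
            return p.jaro_winkler(a, b) >= params.name_match_threshold
        return a == b

    expected = sum(agree(a, b) for a, b in pairs) / len(pairs)
    expected = min(max(expected, 1e-6), 1 - 1e-6)
    assert p.estimate_u(registry30, field, params) == pytest.approx(expected)


def test_with_estimated_u_produces_valid_parameters(registry100):
    est = p.MatchParameters.default().with_estimated_u(registry100, seed=0)
    for f in p.FIELDS:
        assert 0.0 < est.u[f] < 1.0


# -- config round-trip ------------------------------------------------------------

def test_parameters_yaml_roundtrip(tmp_path):
    params = p.MatchParameters(top_k=7, yob_tolerance=3)
    path = tmp_path / "cfg.yaml"
    params.to_yaml(path)
    back = p.MatchParameters.from_yaml(path)
    assert back == params


def test_parameters_validation():
    with pytest.raises(p.ParameterError):
        p.MatchParameters(m={"name1": 1.5})
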