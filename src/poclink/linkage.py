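"""Fellegi–Sunter match scoring and candidate ranking.

Each comparison field i has a match probability m_i = P(agree | true
match) and a chance-agreement probability u_i = P(agree | true
non-match).  On agreement a field contributes log2(m_i/u_i) to the match
score; on disagreement log2((1-m_i)/(1-u_i)); a field missing on either
side contributes 0 (no reward, no penalty).  The score of a
query/record pair is the sum over fields, assuming field independence.

Agreement rules follow the fieldwork conventions: each reported name
agrees when its best-assignment Jaro–Winkler pairing scores >= 0.8; sex,
village and sub-village require exact equality; year of birth may differ
by up to two years; month and day of birth must be exact; the
household-member and ten-cell-leader name groups agree when any assigned
name pair reaches the 0.8 threshold.

``search`` scores every registry record (no blocking — a full scan is
fast enough at registry sizes of ~10^5) and returns the top-k by score,
ties broken by record ID for determinism.  Candidates carry the
match-time warnings a reviewer must see before assigning a match: a
birth-year gap above 10 years, or a summed name score at or below 1.6.
"""

from __future__ import annotations

import enum
import itertools
import math
import random
from dataclasses import dataclass, field as _dcfield, replace
from typing import Optional, Sequence

import yaml

from .errors import EstimationError, ParameterError, UnsearchableQueryError
from .registry import Registry, RegistryRecord, SearchQuery
from .strcompare import best_name_assignment, jaro_winkler

__all__ = [
    "Agreement",
    "FIELDS",
    "MatchParameters",
    "AgreementVector",
    "CandidateMatch",
    "evaluate_agreement",
    "field_weight",
    "match_score",
    "search",
    "match_warnings",
    "estimate_u",
    "AGE_GAP",
    "LOW_NAME_SCORE",
]


class Agreement(enum.Enum):
    AGREE = "agree"
    DISAGREE = "disagree"
    MISSING = "missing"


#: Comparison fields, in score-report order.
FIELDS = (
    "name1", "name2", "name3",
    "sex", "birth_year", "birth_month", "birth_day",
    "village", "subvillage",
    "hh_member_names", "tcl_names",
)

# Match probabilities: adopted defaults for a rural-HDSS setting
# (names recorded carefully but subject to spelling variation; day of
# birth the least reliably recalled field).
_DEFAULT_M = {
    "name1": 0.9, "name2": 0.9, "name3": 0.9,
    "sex": 0.95,
    "birth_year": 0.9, "birth_month": 0.8, "birth_day": 0.7,
    "village": 0.9, "subvillage": 0.9,
    "hh_member_names": 0.8, "tcl_names": 0.8,
}

# Fallback chance-agreement rates, used only when u has not been
# estimated from the loaded registry (estimate_u is the preferred
# route).  Values are plausible for the setting: ~50/50 sex split,
# birth years spread over ~6 decades with a +/-2-year window, a handful
# of villages, many sub-villages, large name pools.
_DEFAULT_U = {
    "name1": 0.01, "name2": 0.01, "name3": 0.01,
    "sex": 0.5,
    "birth_year": 0.08, "birth_month": 1 / 12, "birth_day": 1 / 31,
    "village": 0.1, "subvillage": 0.02,
    "hh_member_names": 0.02, "tcl_names": 0.05,
}

AGE_GAP = "AGE_GAP"
LOW_NAME_SCORE = "LOW_NAME_SCORE"

_U_CLAMP = 1e-6


@dataclass(frozen=True)
class MatchParameters:
    """Per-field m/u probabilities plus agreement thresholds.

    ``name_match_threshold``: Jaro–Winkler score at or above which a
    paired name counts as agreeing (default 0.8).
    ``yob_tolerance``: maximum absolute birth-year difference that still
    counts as agreement (default 2 years).
    ``top_k``: number of ranked candidates returned per search (default 20).
    ``age_gap_years`` / ``low_name_score``: warning thresholds — flag a
    candidate whose birth year differs by more than 10 years, or whose
    summed name score is at or below 1.6.
    """

    m: dict = _dcfield(default_factory=lambda: dict(_DEFAULT_M))
    u: dict = _dcfield(default_factory=lambda: dict(_DEFAULT_U))
    name_match_threshold: float = 0.8
    yob_tolerance: int = 2
    top_k: int = 20
    age_gap_years: int = 10
    low_name_score: float = 1.6

    def __post_init__(self):
        for fname in FIELDS:
            for label, probs in (("m", self.m), ("u", self.u)):
                if fname not in probs:
                    raise ParameterError(f"missing {label}[{fname!r}]")
                p = probs[fname]
                if not (0.0 < p < 1.0):
                    raise ParameterError(
                        f"{label}[{fname!r}] = {p} outside (0, 1)"
                    )

    @classmethod
    def default(cls) -> "MatchParameters":
        return cls()

    def with_estimated_u(
        self, registry: Registry, seed: Optional[int] = None
    ) -> "MatchParameters":
        """Replace every u with its chance-agreement estimate on ``registry``."""
        u = {
            fname: estimate_u(registry, fname, params=self, seed=seed)
            for fname in FIELDS
        }
        return replace(self, u=u)

    # -- config file round-trip ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "m": dict(self.m),
            "u": dict(self.u),
            "name_match_threshold": self.name_match_threshold,
            "yob_tolerance": self.yob_tolerance,
            "top_k": self.top_k,
            "age_gap_years": self.age_gap_years,
            "low_name_score": self.low_name_score,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MatchParameters":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        base = cls.default()
        m = dict(base.m)
        m.update(data.get("m") or {})
        u = dict(base.u)
        u.update(data.get("u") or {})
        kwargs = {
            k: data[k]
            for k in (
                "name_match_threshold", "yob_tolerance", "top_k",
                "age_gap_years", "low_name_score",
            )
            if k in data
        }
        return cls(m=m, u=u, **kwargs)


@dataclass(frozen=True)
class AgreementVector:
    """Per-field agreement states for one query/record pair, plus the raw
    paired name scores (patient names only) and their total."""

    states: dict
    name_pair_scores: tuple[float, ...]
    name_score_total: float


@dataclass(frozen=True)
class CandidateMatch:
    """One ranked registry record in a search result."""

    record_id: str
    score: float
    rank: int
    field_weights: dict
    warnings: tuple[str, ...]
    name_score_total: float


def _group_agreement(
    query_tokens: Sequence[str],
    record_tokens: Sequence[str],
    threshold: float,
) -> Agreement:
    if not query_tokens or not record_tokens:
        return Agreement.MISSING
    paired, _ = best_name_assignment(query_tokens, record_tokens)
    return (
        Agreement.AGREE if any(s >= threshold for s in paired) else Agreement.DISAGREE
    )


def evaluate_agreement(
    query: SearchQuery,
    record: RegistryRecord,
    params: MatchParameters,
    household_names: Sequence[str] = (),
) -> AgreementVector:
    """Apply each field's agreement rule to one query/record pair.

    ``household_names`` are the name tokens of the record's household
    co-residents (supplied by :func:`search` from the registry); without
    them the household-member field is treated as missing.
    """
    if not query.searchable:
        raise UnsearchableQueryError("query has no names or reports residence outside the area")
    states: dict = {}

    if record.names:
        paired, total = best_name_assignment(query.names, record.names)
    else:  # registry invariant forbids this, but stay defensive
        paired, total = (), 0.0
    for i in range(3):
        fname = f"name{i + 1}"
        if i < len(paired):
            states[fname] = (
                Agreement.AGREE
                if paired[i] >= params.name_match_threshold
                else Agreement.DISAGREE
            )
        else:
            states[fname] = Agreement.MISSING

    def exact(qv, rv):
        if qv is None or rv is None:
            return Agreement.MISSING
        return Agreement.AGREE if qv == rv else Agreement.DISAGREE

    states["sex"] = exact(query.sex, record.sex)
    if query.birth_year is None or record.birth_year is None:
        states["birth_year"] = Agreement.MISSING
    else:
        states["birth_year"] = (
            Agreement.AGREE
            if abs(query.birth_year - record.birth_year) <= params.yob_tolerance
            else Agreement.DISAGREE
        )
    states["birth_month"] = exact(query.birth_month, record.birth_month)
    states["birth_day"] = exact(query.birth_day, record.birth_day)
    states["village"] = exact(query.village, record.village or None)
    states["subvillage"] = exact(query.subvillage, record.subvillage)
    states["hh_member_names"] = _group_agreement(
        query.hh_member_names, household_names, params.name_match_threshold
    )
    states["tcl_names"] = _group_agreement(
        query.tcl_names, record.tcl_names, params.name_match_threshold
    )
    return AgreementVector(states=states, name_pair_scores=paired, name_score_total=total)


def field_weight(m: float, u: float, state: Agreement) -> float:
    """log2 likelihood-ratio weight of one field's agreement state."""
    if not (0.0 < m < 1.0) or not (0.0 < u < 1.0):
        raise ParameterError(f"m={m}, u={u} must lie in (0, 1)")
    if state is Agreement.AGREE:
        return math.log2(m / u)
    if state is Agreement.DISAGREE:
        return math.log2((1.0 - m) / (1.0 - u))
    return 0.0


def _weights(vector: AgreementVector, params: MatchParameters) -> dict:
    return {
        fname: field_weight(params.m[fname], params.u[fname], vector.states[fname])
        for fname in FIELDS
    }


def match_score(
    query: SearchQuery,
    record: RegistryRecord,
    params: MatchParameters,
    household_names: Sequence[str] = (),
) -> float:
    """Summed field weights for one query/record pair."""
    vector = evaluate_agreement(query, record, params, household_names)
    return sum(_weights(vector, params).values())


def match_warnings(
    query: SearchQuery,
    record: RegistryRecord,
    params: MatchParameters = None,
) -> list[str]:
    """Review warnings for a candidate the user is about to assign.

    AGE_GAP: birth years (both present) differ by more than 10 years.
    LOW_NAME_SCORE: the summed best-assignment Jaro–Winkler scores of the
    patient names are at or below 1.6 (boundary inclusive).
    """
    params = params or MatchParameters.default()
    out = []
    if (
        query.birth_year is not None
        and record.birth_year is not None
        and abs(query.birth_year - record.birth_year) > params.age_gap_years
    ):
        out.append(AGE_GAP)
    if query.names and record.names:
        _, total = best_name_assignment(query.names, record.names)
        if total <= params.low_name_score:
            out.append(LOW_NAME_SCORE)
    return out


def search(
    query: SearchQuery,
    registry: Registry,
    params: Optional[MatchParameters] = None,
) -> list[CandidateMatch]:
    """Score every registry record against the query and return the top-k.

    Full scan, no blocking.  Candidates are sorted by score descending,
    ties broken by record ID ascending; ranks run 1..k contiguously.
    Raises :class:`UnsearchableQueryError` for queries with no name or an
    outside-area residence.
    """
    params = params or MatchParameters.default()
    query = query.normalized()
    if not query.searchable:
        raise UnsearchableQueryError(
            "query has no names or reports residence outside the area"
        )
    scored = []
    for record in registry:
        conames = registry.household_conames(record.record_id)
        vector = evaluate_agreement(query, record, params, conames)
        weights = _weights(vector, params)
        scored.append((sum(weights.values()), record, weights, vector))
    scored.sort(key=lambda item: (-item[0], item[1].record_id))
    out = []
    for rank, (score, record, weights, vector) in enumerate(
        scored[: params.top_k], start=1
    ):
        out.append(
            CandidateMatch(
                record_id=record.record_id,
                score=score,
                rank=rank,
                field_weights=weights,
                warnings=tuple(match_warnings(query, record, params)),
                name_score_total=vector.name_score_total,
            )
        )
    return out


# ---------------------------------------------------------------------------
# u-probability estimation

_EXACT_FIELDS = {"sex", "birth_month", "birth_day", "village", "subvillage"}


def _field_values(registry: Registry, fname: str) -> list:
    vals = []
    for rec in registry:
        if fname == "name1":
            v = rec.names[0] if len(rec.names) >= 1 else None
        elif fname == "name2":
            v = rec.names[1] if len(rec.names) >= 2 else None
        elif fname == "name3":
            v = rec.names[2] if len(rec.names) >= 3 else None
        elif fname == "hh_member_names":
            v = None  # handled pairwise on records
        elif fname == "tcl_names":
            v = rec.tcl_names or None
        else:
            v = getattr(rec, fname)
        if v is not None and v != "":
            vals.append(v)
    return vals


def estimate_u(
    registry: Registry,
    fname: str,
    params: Optional[MatchParameters] = None,
    max_pairs: int = 100_000,
    seed: Optional[int] = None,
) -> float:
    """Chance-agreement probability of field ``fname``: the probability
    that two distinct randomly drawn records agree under that field's
    agreement rule.

    Exact-match fields use the closed form sum_c f_c (f_c - 1) / (n (n - 1))
    over category counts.  Tolerance and threshold fields enumerate all
    pairs when there are at most ``max_pairs`` of them and otherwise
    sample ``max_pairs`` pairs (seeded).  The result is clamped to
    (1e-6, 1 - 1e-6) so weights stay finite.
    """
    params = params or MatchParameters.default()
    threshold = params.name_match_threshold

    if fname in _EXACT_FIELDS:
        vals = _field_values(registry, fname)
        n = len(vals)
        if n < 2:
            raise EstimationError(f"{fname}: fewer than 2 non-missing values")
        counts: dict = {}
        for v in vals:
            counts[v] = counts.get(v, 0) + 1
        u = sum(c * (c - 1) for c in counts.values()) / (n * (n - 1))
        return min(max(u, _U_CLAMP), 1.0 - _U_CLAMP)

    if fname == "birth_year":
        vals = _field_values(registry, fname)
        agree = lambda a, b: abs(a - b) <= params.yob_tolerance  # noqa: E731
    elif fname in ("name1", "name2", "name3"):
        vals = _field_values(registry, fname)
        agree = lambda a, b: jaro_winkler(a, b) >= threshold  # noqa: E731
    elif fname == "tcl_names":
        vals = _field_values(registry, fname)
        agree = (
            lambda a, b: _group_agreement(a, b, threshold) is Agreement.AGREE
        )  # noqa: E731
    elif fname == "hh_member_names":
        # chance that a random person's name matches someone in a random
        # other household: compare each record's names against another
        # record's household co-resident names
        recs = [r for r in registry if r.names]
        if len(recs) < 2:
            raise EstimationError(f"{fname}: fewer than 2 usable records")
        rng = random.Random(seed)
        n_pairs = min(max_pairs, len(recs) * (len(recs) - 1))
        hits = 0
        used = 0
        for _ in range(n_pairs):
            a, b = rng.sample(recs, 2)
            conames = registry.household_conames(b.record_id)
            if a.household_id == b.household_id or not conames:
                continue
            used += 1
            if _group_agreement(a.names, conames, threshold) is Agreement.AGREE:
                hits += 1
        if used == 0:
            raise EstimationError(f"{fname}: no comparable record pairs")
        return min(max(hits / used, _U_CLAMP), 1.0 - _U_CLAMP)
    else:
        raise ParameterError(f"unknown field {fname!r}")

    n = len(vals)
    if n < 2:
        raise EstimationError(f"{fname}: fewer than 2 non-missing values")
    total_pairs = n * (n - 1) // 2
    if total_pairs <= max_pairs:
        hits = sum(
            1 for a, b in itertools.combinations(vals, 2) if agree(a, b)
        )
        u = hits / total_pairs
    else:
        rng = random.Random(seed)
        hits = 0
        for _ in range(max_pairs):
            a, b = rng.sample(vals, 2)
            if agree(a, b):
                hits += 1
        u = hits / max_pairs
    return min(max(u, _U_CLAMP), 1.0 - _U_CLAMP)
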