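"""Jaro and Jaro–Winkler string similarity, and multi-name comparison.

Names reported at a clinic desk differ from registry spellings by typos,
nicknames and — commonly in this setting — by order (first and second
name switched).  Single tokens are compared with the Jaro–Winkler
similarity; lists of up to three names are compared by the one-to-one
pairing that maximises the summed similarity, so a swapped name order
still scores as a perfect match and no registry name is credited twice.

The Jaro similarity of two strings counts characters that match within a
sliding window of half the longer length, discounted by transpositions:

    jaro = (m/|a| + m/|b| + (m - t)/m) / 3

with m matching characters and t half the number of out-of-order
matches.  The Winkler variant adds a boost for a shared prefix of up to
four characters, ``jw = jaro + l * p * (1 - jaro)`` with prefix scale
p = 0.1 and no pre-boost threshold.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["jaro", "jaro_winkler", "best_name_assignment"]

_PREFIX_SCALE = 0.1
_MAX_PREFIX = 4


def jaro(a: str, b: str) -> float:
    """Jaro similarity of two tokens, in [0, 1]."""
    if a == b:
        return 1.0 if a else 0.0
    if not a or not b:
        return 0.0
    la, lb = len(a), len(b)
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    matched_a = [False] * la
    matched_b = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not matched_b[j] and b[j] == ca:
                matched_a[i] = True
                matched_b[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: matched characters out of relative order, halved
    bj = [b[j] for j in range(lb) if matched_b[j]]
    k = 0
    trans = 0
    for i in range(la):
        if matched_a[i]:
            if a[i] != bj[k]:
                trans += 1
            k += 1
    t = trans // 2
    return (m / la + m / lb + (m - t) / m) / 3.0


@lru_cache(maxsize=1 << 18)
def jaro_winkler(a: str, b: str) -> float:
    """Jaro–Winkler similarity (prefix scale 0.1, max prefix 4, no boost
    threshold).  Symmetric; 1.0 iff the tokens are identical and non-empty."""
    j = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == _MAX_PREFIX:
            break
        prefix += 1
    return j + prefix * _PREFIX_SCALE * (1.0 - j)


def best_name_assignment(
    query_names: Sequence[str], record_names: Sequence[str]
) -> tuple[tuple[float, ...], float]:
    """Optimal one-to-one pairing of reported names against registry names.

    All pairwise Jaro–Winkler scores are computed and the assignment
    maximising their sum is selected (Hungarian algorithm); names left
    unpaired on the longer side are ignored.  Returns the paired scores
    (in query-name order of the paired subset) and their sum.

    Raises ``ValueError`` if either list is empty — the caller treats
    that as a missing field.
    """
    if not query_names or not record_names:
        raise ValueError("best_name_assignment requires non-empty name lists")
    scores = np.array(
        [[jaro_winkler(q, r) for r in record_names] for q in query_names]
    )
    rows, cols = linear_sum_assignment(scores, maximize=True)
    paired = tuple(float(scores[i, j]) for i, j in sorted(zip(rows, cols)))
    return paired, float(sum(paired))
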