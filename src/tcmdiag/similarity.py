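"""LCS-based fuzzy similarity between symptom lists.

A user-supplied symptom description rarely matches the library's
technical term letter for letter.  Each input word is scored against a
candidate list by the longest-common-subsequence ratio

    weight(a, b) = len(lcs(a, b)) / max(len(a), len(b)),

and a whole input set against a library entry by

    sim(input, list) = num(weight = 1) * sum(weight) / list.size,

where the sum runs over the input words (each paired with its best list
match), num(weight = 1) counts exact matches, and list.size is the
candidate entry's symptom count.  The product form makes sim a ranking
value, not a probability: it is 0 without at least one exact match and
equals m when the input reproduces an m-symptom entry exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .extract import MappingEntry, MappingTable

__all__ = [
    "MatchWeight",
    "SimilarityScore",
    "best_weight",
    "lcs_length",
    "rank_candidates",
    "set_similarity",
    "word_weight",
]


@dataclass(frozen=True)
class MatchWeight:
    """LCS weight of one word pair."""

    weight: float
    lcs_len: int
    is_exact: bool


@dataclass(frozen=True, order=True)
class SimilarityScore:
    """Decomposition of the set similarity: sim = exact_count * weight_sum / list_size."""

    sim: float
    exact_count: int
    weight_sum: float
    list_size: int


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence of two character strings."""
    if not a or not b:
        return 0
    if len(b) < len(a):
        a, b = b, a
    prev = [0] * (len(a) + 1)
    for cb in b:
        curr = [0]
        best = 0
        for i, ca in enumerate(a, start=1):
            best = prev[i - 1] + 1 if ca == cb else max(prev[i], curr[i - 1])
            curr.append(best)
        prev = curr
    return prev[-1]


def word_weight(a: str, b: str) -> MatchWeight:
    """LCS ratio of two labels: len(lcs)/max(len); 1 iff the labels are equal."""
    if not a and not b:
        raise ValueError("weight is undefined for two empty strings")
    lcs = lcs_length(a, b)
    weight = lcs / max(len(a), len(b))
    return MatchWeight(weight=weight, lcs_len=lcs, is_exact=weight == 1.0)


def best_weight(
    query: str, labels: Sequence[str]
) -> tuple[MatchWeight, str]:
    """Best-matching label for a query word; ties go to the earliest label."""
    if not labels:
        raise ValueError("candidate label list must be non-empty")
    best: tuple[MatchWeight, str] | None = None
    for label in labels:
        mw = word_weight(query, label)
        if best is None or mw.weight > best[0].weight:
            best = (mw, label)
            if mw.is_exact:
                break
    assert best is not None
    return best


def set_similarity(
    input_set: Sequence[str],
    list_set: Sequence[str],
    smoothing: float = 0.0,
) -> SimilarityScore:
    """Fuzzy similarity of an input symptom list against a candidate list.

    Each input symptom is paired with its best list match; the score is
    ``exact_count * weight_sum / list_size`` with ``list_size`` the
    candidate list's length.  ``smoothing`` > 0 replaces the exact-match
    multiplier by ``exact_count + smoothing`` so that partially matching
    entries can still be ranked; the default is the literal formula.
    """
    if not input_set or not list_set:
        raise ValueError("both symptom lists must be non-empty")
    weight_sum = 0.0
    exact_count = 0
    for query in input_set:
        mw, _ = best_weight(query, list_set)
        weight_sum += mw.weight
        exact_count += mw.is_exact
    multiplier = exact_count + smoothing
    return SimilarityScore(
        sim=multiplier * weight_sum / len(list_set),
        exact_count=exact_count,
        weight_sum=weight_sum,
        list_size=len(list_set),
    )


def rank_candidates(
    input_set: Sequence[str],
    table: MappingTable,
    kind: str,
    smoothing: float = 0.0,
) -> list[tuple[MappingEntry, SimilarityScore]]:
    """Score all library entries of a kind and sort best-first.

    Order: sim descending, then exact_count descending, then name
    ascending (so all-zero scores list alphabetically).
    """
    entries = table.entries(kind)
    if not entries:
        raise ValueError(f"mapping table has no entries of kind {kind!r}")
    scored = [
        (e, set_similarity(input_set, e.sorted_symptoms, smoothing=smoothing))
        for e in entries
    ]
    scored.sort(key=lambda es: (-es[1].sim, -es[1].exact_count, es[0].entity_name))
    return scored
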