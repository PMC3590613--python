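"""Ontology-based relation refinement of an initial candidate syndrome.

After the fuzzy ranking picks a candidate, the crisp set relation between
the input symptoms S and the candidate's symptom set T decides how the
ontology rectifies the answer:

* S = T  — the candidate and its equivalent names are perfect answers;
* S ⊃ T  — the input covers more than the candidate: compounds that
  subsume the candidate may fit better;
* S ⊂ T  — the candidate over-specifies: its superclasses (more general
  patterns) are considered;
* S ∩ T  — a genuine partial overlap: the input is decomposed greedily
  into several co-occurring syndromes;
* disjoint — the candidate stands unchanged, with a warning.

Refined candidates are re-scored against their ontology-closed
(effective) symptom sets, so a compound whose parts jointly explain the
input can overtake the parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .extract import MappingTable
from .ontology import (
    SyndromeOntology,
    ancestors,
    effective_symptoms,
    equivalence_set,
    subsumers_of,
)
from .similarity import SimilarityScore, set_similarity

__all__ = [
    "DecompositionConfig",
    "DecompositionResult",
    "RefinedCandidate",
    "RefinementTrace",
    "RelationKind",
    "decompose_partial",
    "match_relation",
    "refine",
]

logger = logging.getLogger(__name__)


class RelationKind(Enum):
    """Crisp set relation between input symptoms S and candidate set T."""

    EQUAL = "equal"
    INPUT_SUPERSET = "input_superset"  # S ⊃ T
    INPUT_SUBSET = "input_subset"  # S ⊂ T
    PARTIAL = "partial"  # S ∩ T above the overlap threshold
    DISJOINT = "disjoint"


@dataclass(frozen=True)
class RefinedCandidate:
    """A candidate produced by refinement, with its provenance and re-score."""

    name: str
    provenance: str  # self | equivalent | superclass | subsumer | decomposition
    score: SimilarityScore | None = None
    effective: frozenset[str] = frozenset()


@dataclass
class RefinementTrace:
    """Audit record of one refinement pass."""

    initial: str
    relation: RelationKind
    candidates: list[RefinedCandidate] = field(default_factory=list)
    decomposition: "DecompositionResult | None" = None


@dataclass(frozen=True)
class DecompositionConfig:
    """Stopping rules of the greedy decomposition into combined syndromes."""

    min_remainder: int = 1  # stop once fewer unmatched symptoms remain
    min_score: float = 0.0  # a component must score strictly above this
    max_components: int = 4


@dataclass
class DecompositionResult:
    """Greedy cover of the input by several co-occurring syndromes."""

    components: list[str]
    residual: set[str]
    no_candidate: bool = False  # nothing ever scored above threshold


def match_relation(
    S: Iterable[str], T: Iterable[str], overlap_threshold: float = 0.3
) -> RelationKind:
    """Classify the relation between input set S and candidate set T.

    Membership is exact normalised equality; partial overlap requires
    Jaccard(S, T) >= overlap_threshold, anything weaker is disjoint.
    """
    s, t = set(S), set(T)
    if not s or not t:
        raise ValueError("both symptom sets must be non-empty")
    if not 0.0 < overlap_threshold <= 1.0:
        raise ValueError(f"overlap_threshold must be in (0, 1], got {overlap_threshold}")
    matched = s & t
    if s == t:
        return RelationKind.EQUAL
    if matched == t:  # T ⊂ S strictly
        return RelationKind.INPUT_SUPERSET
    if matched == s:  # S ⊂ T strictly
        return RelationKind.INPUT_SUBSET
    if matched and len(matched) / len(s | t) >= overlap_threshold:
        return RelationKind.PARTIAL
    return RelationKind.DISJOINT


def _score_against_effective(
    name: str,
    provenance: str,
    input_set: Sequence[str],
    ont: SyndromeOntology,
    table: MappingTable,
) -> RefinedCandidate:
    effective = effective_symptoms(ont, table, name)
    score: SimilarityScore | None = None
    if effective:
        score = set_similarity(list(input_set), sorted(effective))
    return RefinedCandidate(
        name=name, provenance=provenance, score=score, effective=effective
    )


def _sort_candidates(cands: list[RefinedCandidate]) -> list[RefinedCandidate]:
    def key(c: RefinedCandidate):
        s = c.score
        return (-(s.sim if s else 0.0), -(s.exact_count if s else 0), c.name)

    return sorted(cands, key=key)


def refine(
    candidate: str,
    rel: RelationKind,
    ont: SyndromeOntology,
    table: MappingTable,
    input_set: Sequence[str],
    decomposition_config: DecompositionConfig = DecompositionConfig(),
) -> RefinementTrace:
    """Expand an initial candidate according to its set relation.

    Every refined candidate is re-scored against its effective
    (ontology-closed) symptom set; the trace lists them best-first and
    never comes back empty — the initial candidate is always included.
    """
    trace = RefinementTrace(initial=candidate, relation=rel)
    names: list[tuple[str, str]] = [(candidate, "self")]
    if rel is RelationKind.EQUAL:
        names += [
            (n, "equivalent") for n in sorted(equivalence_set(ont, candidate) - {candidate})
        ]
    elif rel is RelationKind.INPUT_SUPERSET:
        names += [(n, "subsumer") for n in sorted(subsumers_of(ont, candidate))]
    elif rel is RelationKind.INPUT_SUBSET:
        names += [(n, "superclass") for n in sorted(ancestors(ont, candidate))]
    elif rel is RelationKind.PARTIAL:
        decomp = decompose_partial(input_set, table, ont, decomposition_config)
        trace.decomposition = decomp
        names += [
            (n, "decomposition") for n in decomp.components if n != candidate
        ]
    else:  # DISJOINT
        logger.warning(
            "input symptoms are disjoint from candidate %r; no refinement applied",
            candidate,
        )

    seen: set[str] = set()
    cands: list[RefinedCandidate] = []
    for name, provenance in names:
        if name in seen:
            continue
        seen.add(name)
        cands.append(
            _score_against_effective(name, provenance, input_set, ont, table)
        )
    trace.candidates = _sort_candidates(cands)
    return trace


def decompose_partial(
    S: Sequence[str],
    table: MappingTable,
    ont: SyndromeOntology,
    config: DecompositionConfig = DecompositionConfig(),
) -> DecompositionResult:
    """Greedily cover the input by several syndromes (combined diagnosis).

    Repeatedly ranks the library's syndromes against the unmatched
    remainder (scored on effective symptom sets), keeps the best one,
    removes the symptoms it explains, and recurses on the rest until the
    remainder is too small, nothing scores above ``min_score``, or
    ``max_components`` is reached.
    """
    if not S:
        raise ValueError("input symptom set must be non-empty")
    remaining = list(dict.fromkeys(S))  # order-preserving
    components: list[str] = []
    entries = table.entries("syndrome")
    effective_cache = {
        e.entity_name: effective_symptoms(ont, table, e.entity_name) for e in entries
    }
    while (
        len(remaining) >= max(config.min_remainder, 1)
        and len(components) < config.max_components
    ):
        best_name: str | None = None
        best_score: SimilarityScore | None = None
        for name in sorted(effective_cache):
            if name in components or not effective_cache[name]:
                continue
            score = set_similarity(remaining, sorted(effective_cache[name]))
            if (
                best_score is None
                or (score.sim, score.exact_count) > (best_score.sim, best_score.exact_count)
            ):
                best_name, best_score = name, score
        if best_name is None or best_score is None or best_score.sim <= config.min_score:
            break
        matched = [s for s in remaining if s in effective_cache[best_name]]
        if not matched:  # guarantees termination
            break
        components.append(best_name)
        remaining = [s for s in remaining if s not in effective_cache[best_name]]
    return DecompositionResult(
        components=components,
        residual=set(remaining),
        no_candidate=not components,
    )
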