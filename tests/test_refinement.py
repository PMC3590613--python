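"""Relation classification, ontology refinement and greedy decomposition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcmdiag import (
    ClinicalCase,
    DecompositionConfig,
    RelationKind,
    SyndromeOntology,
    build_mapping_table,
    decompose_partial,
    load_ontology,
    match_relation,
    refine,
)
from tcmdiag.extract import MappingEntry, MappingTable

from conftest import EQUIVALENCE_XML, SUBSUME_XML


def table_of(**symptoms_by_syndrome):
    return MappingTable(
        MappingEntry("syndrome", name, frozenset(symptoms), support=1)
        for name, symptoms in symptoms_by_syndrome.items()
    )


# -- match_relation ---------------------------------------------------------


@pytest.mark.parametrize(
    "S,T,expected",
    [
        ({"a", "b", "c"}, {"a", "b"}, RelationKind.INPUT_SUPERSET),
        ({"a", "b"}, {"a", "b"}, RelationKind.EQUAL),
        ({"a", "b"}, {"a", "b", "c"}, RelationKind.INPUT_SUBSET),
        ({"a", "x"}, {"a", "y"}, RelationKind.PARTIAL),  # Jaccard 1/3 >= 0.3
        ({"a", "x", "y", "z"}, {"a", "p", "q", "r"}, RelationKind.DISJOINT),  # 1/7 < 0.3
        ({"a"}, {"b"}, RelationKind.DISJOINT),
    ],
)
def test_match_relation_cases(S, T, expected):
    assert match_relation(S, T, overlap_threshold=0.3) is expected


def test_match_relation_rejects_empty_sets():
    with pytest.raises(ValueError):
        match_relation(set(), {"a"})
    with pytest.raises(ValueError):
        match_relation({"a"}, set())


@given(
    st.sets(st.sampled_from("abcdefg"), min_size=1, max_size=6),
    st.sets(st.sampled_from("abcdefg"), min_size=1, max_size=6),
    st.floats(min_value=0.05, max_value=1.0),
)
@settings(max_examples=200, derandomize=True)
def test_match_relation_exhaustive_and_exclusive(S, T, threshold):
    """Exactly one relation kind fits any pair of sets under a fixed threshold."""
    rel = match_relation(S, T, overlap_threshold=threshold)
    assert rel in RelationKind
    # re-derive the expected kind independently
    if S == T:
        assert rel is RelationKind.EQUAL
    elif T < S:
        assert rel is RelationKind.INPUT_SUPERSET
    elif S < T:
        assert rel is RelationKind.INPUT_SUBSET
    elif S & T and len(S & T) / len(S | T) >= threshold:
        assert rel is RelationKind.PARTIAL
    else:
        assert rel is RelationKind.DISJOINT


# -- refine -----------------------------------------------------------------


def test_refine_equal_adds_equivalents():
    ont = load_ontology(EQUIVALENCE_XML)
    table = table_of(**{"Deficient cold syndrome": {"chills", "pale tongue"}})
    trace = refine(
        "Deficient cold syndrome",
        RelationKind.EQUAL,
        ont,
        table,
        ["chills", "pale tongue"],
    )
    names = {c.name for c in trace.candidates}
    assert {"Cold syndrome", "Yang deficient syndrome"} <= names


def test_refine_input_superset_adds_subsumers():
    ont = load_ontology(SUBSUME_XML)
    table = table_of(
        **{
            "Qi stagnation syndrome": {"distension", "sighing"},
            "Blood stasis syndrome": {"fixed pain", "dark tongue"},
        }
    )
    trace = refine(
        "Qi stagnation syndrome",
        RelationKind.INPUT_SUPERSET,
        ont,
        table,
        ["distension", "sighing", "fixed pain", "dark tongue"],
    )
    assert trace.candidates[0].name == "Qi stagnation and blood stasis"
    assert trace.candidates[0].provenance == "subsumer"


def test_refine_input_subset_adds_superclasses():
    ont = SyndromeOntology(subclass_edges={("specific", "general")})
    table = table_of(specific={"a", "b", "c"}, general={"a"})
    trace = refine("specific", RelationKind.INPUT_SUBSET, ont, table, ["a"])
    assert {c.name for c in trace.candidates} == {"specific", "general"}
    provs = {c.name: c.provenance for c in trace.candidates}
    assert provs["general"] == "superclass"


def test_refine_disjoint_falls_back_to_self():
    ont = SyndromeOntology()
    table = table_of(only={"a"})
    trace = refine("only", RelationKind.DISJOINT, ont, table, ["z"])
    assert [c.name for c in trace.candidates] == ["only"]


def test_refine_never_empty_even_for_unknown_candidate():
    trace = refine("ghost", RelationKind.EQUAL, SyndromeOntology(), table_of(x={"a"}), ["a"])
    assert [c.name for c in trace.candidates] == ["ghost"]


def test_refined_candidates_rescored_on_effective_sets():
    """A compound subsuming both parts outscores each part on the union input."""
    ont = SyndromeOntology(subsume_edges={("w", "b"), ("w", "c")})
    table = table_of(b={"x1", "x2"}, c={"y1", "y2"})
    query = ["x1", "x2", "y1", "y2"]
    trace = refine("b", RelationKind.INPUT_SUPERSET, ont, table, query)
    by_name = {c.name: c for c in trace.candidates}
    assert by_name["w"].score.sim >= by_name["b"].score.sim
    assert trace.candidates[0].name == "w"


# -- decompose_partial ------------------------------------------------------


def test_decompose_recovers_two_disjoint_signatures():
    table = table_of(alpha={"a1", "a2", "a3"}, beta={"b1", "b2", "b3"}, gamma={"zz"})
    result = decompose_partial(
        ["a1", "a2", "a3", "b1", "b2", "b3"], table, SyndromeOntology()
    )
    assert result.components == ["alpha", "beta"]
    assert result.residual == set()
    assert not result.no_candidate


def test_decompose_single_signature_single_pass():
    table = table_of(alpha={"a1", "a2"})
    result = decompose_partial(["a1", "a2"], table, SyndromeOntology())
    assert result.components == ["alpha"]


def test_decompose_reports_unmatched_residual():
    table = table_of(alpha={"a1", "a2"}, beta={"b1", "b2"}, gamma={"g1"})
    result = decompose_partial(
        ["a1", "a2", "b1", "b2", "mystery"], table, SyndromeOntology()
    )
    assert result.components[:2] == ["alpha", "beta"]
    assert "mystery" in result.residual


def test_decompose_no_scoring_candidate_flags():
    table = table_of(alpha={"a1", "a2"})
    result = decompose_partial(["zz", "yy"], table, SyndromeOntology())
    assert result.components == []
    assert result.no_candidate


def test_decompose_respects_max_components():
    table = table_of(s1={"a"}, s2={"b"}, s3={"c"}, s4={"d"}, s5={"e"})
    result = decompose_partial(
        ["a", "b", "c", "d", "e"],
        table,
        SyndromeOntology(),
        DecompositionConfig(max_components=2),
    )
    assert len(result.components) == 2
    assert len(set(result.components)) == 2


def test_decompose_components_pairwise_distinct_and_terminates():
    cases = [
        ClinicalCase("d", f"syn{i}", tuple(f"s{i}{j}" for j in range(3)))
        for i in range(6)
    ]
    table = build_mapping_table(cases)
    query = [f"s{i}{j}" for i in range(6) for j in range(3)]
    result = decompose_partial(query, table, SyndromeOntology())
    assert len(result.components) == len(set(result.components))
    assert len(result.components) <= 4  # default cap
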