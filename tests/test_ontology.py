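"""Ontology parsing and equivalence/inheritance/subsume reasoning."""

import random

import pytest

from tcmdiag import (
    ClinicalCase,
    InvalidOntologyError,
    SyndromeOntology,
    ancestors,
    build_mapping_table,
    effective_symptoms,
    equivalence_set,
    load_ontology,
    ontology_stats,
    subsumed_parts,
    subsumers_of,
    write_ontology_tsv,
)
from tcmdiag.extract import MappingEntry, MappingTable

from conftest import EQUIVALENCE_XML, SUBSUME_XML

COMPOUND = "Qi stagnation and blood stasis"


def table_of(**symptoms_by_syndrome):
    return MappingTable(
        MappingEntry("syndrome", name, frozenset(symptoms), support=1)
        for name, symptoms in symptoms_by_syndrome.items()
    )


# -- loading ----------------------------------------------------------------


def test_load_equivalence_listing():
    ont = load_ontology(EQUIVALENCE_XML)
    group = equivalence_set(ont, "Deficient cold syndrome")
    assert group == {
        "Deficient cold syndrome",
        "Cold syndrome",
        "Yang deficient syndrome",
    }


def test_load_subsume_listing():
    ont = load_ontology(SUBSUME_XML)
    assert subsumed_parts(ont, COMPOUND) == {
        "Qi stagnation syndrome",
        "Blood stasis syndrome",
    }
    assert subsumers_of(ont, "Qi stagnation syndrome") == {COMPOUND}
    assert ancestors(ont, COMPOUND) == {"Excess syndrome"}
    assert ontology_stats(ont) == {
        "classes": 4,
        "subclass_axioms": 1,
        "equivalent_axioms": 0,
        "subsume_axioms": 2,
    }


def test_load_empty_documents():
    assert load_ontology("").is_empty()
    empty_rdf = (
        '<?xml version="1.0"?><rdf:RDF '
        'xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"/>'
    )
    assert load_ontology(empty_rdf).is_empty()
    assert ontology_stats(SyndromeOntology()) == {
        "classes": 0,
        "subclass_axioms": 0,
        "equivalent_axioms": 0,
        "subsume_axioms": 0,
    }


def test_unknown_restriction_property_skipped_with_warning():
    xml = SUBSUME_XML.replace('rdf:resource="subsume"', 'rdf:resource="partOf"')
    with pytest.warns(UserWarning, match="unknown property"):
        ont = load_ontology(xml)
    assert not ont.subsume_edges


def test_cyclic_subclass_graph_rejected():
    with pytest.raises(InvalidOntologyError, match="cycle"):
        SyndromeOntology(subclass_edges={("a", "b"), ("b", "a")})


def test_tsv_dialect_roundtrip_preserves_axioms():
    ont = SyndromeOntology(
        classes={"lonely"},
        equivalence_axioms={frozenset(("a", "b"))},
        subclass_edges={("child", "parent")},
        subsume_edges={("whole", "part1"), ("whole", "part2")},
    )
    reloaded = load_ontology(write_ontology_tsv(ont))
    assert reloaded.classes == ont.classes
    assert reloaded.equivalence_axioms == ont.equivalence_axioms
    assert reloaded.subclass_edges == ont.subclass_edges
    assert reloaded.subsume_edges == ont.subsume_edges


def test_tsv_dialect_file_roundtrip(tmp_path):
    ont = load_ontology(SUBSUME_XML)
    path = tmp_path / "syn.tsv"
    write_ontology_tsv(ont, path)
    reloaded = load_ontology(path)
    assert reloaded.subsume_edges == ont.subsume_edges
    assert reloaded.classes == ont.classes


# -- reasoning --------------------------------------------------------------


def test_equivalence_reflexive_and_transitive():
    ont = SyndromeOntology(
        equivalence_axioms={frozenset(("a", "b")), frozenset(("b", "c"))}
    )
    assert equivalence_set(ont, "a") == {"a", "b", "c"}
    assert equivalence_set(ont, "unknown") == {"unknown"}


def test_equivalence_induces_partition():
    ont = SyndromeOntology(
        equivalence_axioms={frozenset(("a", "b")), frozenset(("c", "d"))}
    )
    for x in ("a", "b", "c", "d"):
        for y in equivalence_set(ont, x):
            assert x in equivalence_set(ont, y)
    assert equivalence_set(ont, "a").isdisjoint(equivalence_set(ont, "c"))


def test_ancestors_matches_bfs_oracle_on_random_dag():
    """Transitive superclass closure equals independent BFS reachability."""
    rng = random.Random(5)
    nodes = [f"n{i:02d}" for i in range(30)]
    # edges only from lower to higher index: acyclic by construction
    edges = set()
    for i in range(30):
        for j in range(i + 1, 30):
            if rng.random() < 0.1:
                edges.add((nodes[i], nodes[j]))
    ont = SyndromeOntology(subclass_edges=edges)
    adjacency = {}
    for child, parent in edges:
        adjacency.setdefault(child, []).append(parent)
    for start in nodes:
        seen, queue = set(), list(adjacency.get(start, []))
        while queue:
            cur = queue.pop(0)
            if cur in seen:
                continue
            seen.add(cur)
            queue.extend(adjacency.get(cur, []))
        assert ancestors(ont, start) == seen


def test_ancestors_transitive():
    ont = SyndromeOntology(subclass_edges={("a", "b"), ("b", "c")})
    assert ancestors(ont, "a") == {"b", "c"}
    assert ancestors(ont, "c") == set()


def test_parts_of_unknown_name_empty():
    assert subsumed_parts(SyndromeOntology(), "nope") == set()
    assert subsumers_of(SyndromeOntology(), "nope") == set()


# -- effective symptoms -----------------------------------------------------


def test_effective_symptoms_union_of_parts():
    ont = SyndromeOntology(subsume_edges={("a", "b"), ("a", "c")})
    table = table_of(b={"x"}, c={"y"})
    assert effective_symptoms(ont, table, "a") == {"x", "y"}


def test_effective_symptoms_isolated_node():
    table = table_of(a={"p", "q"})
    assert effective_symptoms(SyndromeOntology(), table, "a") == {"p", "q"}


def test_effective_symptoms_inheritance():
    ont = SyndromeOntology(subclass_edges={("child", "parent")})
    table = table_of(parent={"u"}, child={"v"})
    assert effective_symptoms(ont, table, "child") == {"u", "v"}
    assert effective_symptoms(ont, table, "parent") == {"u"}


def test_effective_symptoms_equivalents_contribute():
    ont = SyndromeOntology(equivalence_axioms={frozenset(("a", "b"))})
    table = table_of(a={"x"}, b={"y"})
    assert effective_symptoms(ont, table, "a") == {"x", "y"}


def test_effective_symptoms_recursive_subsume():
    ont = SyndromeOntology(subsume_edges={("top", "mid"), ("mid", "leaf")})
    table = table_of(leaf={"z"}, mid={"m"})
    assert effective_symptoms(ont, table, "top") == {"m", "z"}


def test_effective_symptoms_subsume_cycle_detected():
    ont = SyndromeOntology(subsume_edges={("a", "b"), ("b", "a")})
    with pytest.raises(InvalidOntologyError, match="cycle"):
        effective_symptoms(ont, table_of(a={"x"}, b={"y"}), "a")


def test_effective_symptoms_monotone_under_growth():
    """Adding a subsume edge or a table entry never shrinks any effective set."""
    base_ont = SyndromeOntology(subsume_edges={("w", "b")})
    table = table_of(b={"x"}, c={"y"})
    before = effective_symptoms(base_ont, table, "w")
    grown_ont = SyndromeOntology(subsume_edges={("w", "b"), ("w", "c")})
    after_edge = effective_symptoms(grown_ont, table, "w")
    assert before <= after_edge
    bigger_table = table_of(b={"x", "x2"}, c={"y"})
    assert after_edge <= effective_symptoms(grown_ont, bigger_table, "w")


def test_effective_whole_contains_effective_part():
    ont = SyndromeOntology(subsume_edges={("w", "b"), ("b", "c")})
    table = table_of(b={"x"}, c={"y"}, w={"z"})
    for whole, part in ont.subsume_edges:
        assert effective_symptoms(ont, table, whole) >= effective_symptoms(
            ont, table, part
        )


def test_effective_symptoms_on_heat_table(heat_cases):
    table = build_mapping_table(heat_cases)
    ont = SyndromeOntology()
    assert effective_symptoms(ont, table, "Heat") == {"heat", "dizzy"}


def test_case_data_flows_into_effective_sets():
    cases = [ClinicalCase("d", "part1", ("a", "b")), ClinicalCase("d", "part2", ("c",))]
    table = build_mapping_table(cases)
    ont = SyndromeOntology(subsume_edges={("compound", "part1"), ("compound", "part2")})
    assert effective_symptoms(ont, table, "compound") == {"a", "b", "c"}
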