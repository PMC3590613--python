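"""The syndrome ontology: equivalence, inheritance and subsume reasoning.

Three kinds of inter-syndrome knowledge are modelled, mirroring how the
field encodes them in OWL:

* equivalence — distinct names for the same pattern (``owl:equivalentClass``
  between two named classes);
* inheritance — a sub-syndrome inherits the symptoms associated with its
  super-syndrome (``rdfs:subClassOf``);
* subsume — a compound syndrome captures the union of all symptoms of its
  part syndromes (``owl:equivalentClass`` to an ``owl:Restriction`` on a
  property locally named "subsume" with ``owl:someValuesFrom`` a named
  class).

Two serialisations are read: RDF/XML with the idioms above (via rdflib)
and a simple three-column TSV triple dialect used for fixtures and
round-tripping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union
from urllib.parse import unquote

import networkx as nx
import rdflib
from rdflib.namespace import OWL, RDF, RDFS

__all__ = [
    "InvalidOntologyError",
    "SyndromeOntology",
    "ancestors",
    "effective_symptoms",
    "equivalence_set",
    "load_ontology",
    "ontology_stats",
    "subsumed_parts",
    "subsumers_of",
    "write_ontology_tsv",
]

_BASE_IRI = "http://tcm.example/synont/"

#: predicates of the simple triple dialect
_DIALECT_PREDICATES = ("equivalent", "is_a", "subsume", "class")


class InvalidOntologyError(ValueError):
    """The ontology violates a structural invariant (e.g. a cycle)."""


@dataclass
class SyndromeOntology:
    """Knowledge base of syndrome classes and their inter-relations.

    ``subclass_edges`` are (child, parent) pairs forming a DAG;
    ``subsume_edges`` are (whole, part) pairs; ``equivalence_axioms`` are
    unordered name pairs.
    """

    classes: set[str] = field(default_factory=set)
    equivalence_axioms: set[frozenset[str]] = field(default_factory=set)
    subclass_edges: set[tuple[str, str]] = field(default_factory=set)
    subsume_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair in self.equivalence_axioms:
            self.classes.update(pair)
        for edge in self.subclass_edges | self.subsume_edges:
            self.classes.update(edge)
        self.validate()

    def validate(self) -> None:
        graph = nx.DiGraph(self.subclass_edges)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise InvalidOntologyError(f"subclass graph has a cycle: {cycle}")
        for whole, part in self.subsume_edges:
            if whole == part:
                raise InvalidOntologyError(f"{whole!r} cannot subsume itself")

    def is_empty(self) -> bool:
        return not (
            self.classes
            or self.equivalence_axioms
            or self.subclass_edges
            or self.subsume_edges
        )


# ---------------------------------------------------------------------------
# parsing


def _local_name(term: rdflib.term.Node) -> str:
    text = unquote(str(term))
    for sep in ("#", "/"):
        if sep in text:
            text = text.rsplit(sep, 1)[1]
    return text.strip()


def _load_rdfxml(text: str) -> SyndromeOntology:
    # class names with spaces are legal in the idiom we accept; silence
    # rdflib's per-term complaints about them
    logging.getLogger("rdflib.term").setLevel(logging.ERROR)
    graph = rdflib.Graph()
    graph.parse(data=text, format="xml", publicID=_BASE_IRI)

    classes: set[str] = set()
    equivalences: set[frozenset[str]] = set()
    subclass: set[tuple[str, str]] = set()
    subsume: set[tuple[str, str]] = set()

    for s in graph.subjects(RDF.type, OWL.Class):
        if isinstance(s, rdflib.URIRef):
            classes.add(_local_name(s))

    for s, o in graph.subject_objects(OWL.equivalentClass):
        if not isinstance(s, rdflib.URIRef):
            continue
        subject = _local_name(s)
        if isinstance(o, rdflib.URIRef):
            obj = _local_name(o)
            if subject != obj:
                equivalences.add(frozenset((subject, obj)))
            continue
        # anonymous object: expect an owl:Restriction on "subsume"
        if (o, RDF.type, OWL.Restriction) in graph:
            prop = graph.value(o, OWL.onProperty)
            target = graph.value(o, OWL.someValuesFrom)
            if prop is not None and _local_name(prop) == "subsume":
                if isinstance(target, rdflib.URIRef):
                    subsume.add((subject, _local_name(target)))
            else:
                warnings.warn(
                    f"restriction on unknown property {prop}; axiom skipped",
                    stacklevel=3,
                )

    for s, o in graph.subject_objects(RDFS.subClassOf):
        if isinstance(s, rdflib.URIRef) and isinstance(o, rdflib.URIRef):
            subclass.add((_local_name(s), _local_name(o)))

    return SyndromeOntology(
        classes=classes,
        equivalence_axioms=equivalences,
        subclass_edges=subclass,
        subsume_edges=subsume,
    )


def _load_tsv(text: str) -> SyndromeOntology:
    classes: set[str] = set()
    equivalences: set[frozenset[str]] = set()
    subclass: set[tuple[str, str]] = set()
    subsume: set[tuple[str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise InvalidOntologyError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        subject, predicate, obj = (p.strip() for p in parts)
        if predicate == "equivalent":
            if subject != obj:
                equivalences.add(frozenset((subject, obj)))
        elif predicate == "is_a":
            subclass.add((subject, obj))
        elif predicate == "subsume":
            subsume.add((subject, obj))
        elif predicate == "class":
            classes.add(subject)
        else:
            warnings.warn(
                f"line {lineno}: unknown predicate {predicate!r}; "
                f"expected one of {_DIALECT_PREDICATES}; line skipped",
                stacklevel=3,
            )
    return SyndromeOntology(
        classes=classes,
        equivalence_axioms=equivalences,
        subclass_edges=subclass,
        subsume_edges=subsume,
    )


def load_ontology(source: Union[str, Path]) -> SyndromeOntology:
    """Load a syndrome ontology from RDF/XML or the simple triple dialect.

    ``source`` is a path or a document string; the format is sniffed (a
    document starting with ``<`` is RDF/XML, otherwise the TSV dialect).
    """
    text = str(source)
    if isinstance(source, Path) or (
        "\n" not in text and "\t" not in text and Path(text).is_file()
    ):
        text = Path(source).read_text(encoding="utf-8")
    if text.lstrip().startswith("<"):
        return _load_rdfxml(text)
    return _load_tsv(text)


def write_ontology_tsv(
    ont: SyndromeOntology, path: Union[str, Path, None] = None
) -> str:
    """Serialise to the triple dialect; round-trips all four axiom sets.

    Classes not mentioned by any axiom get an explicit ``class``
    declaration line so that the class set is preserved exactly.
    """
    lines: list[str] = []
    covered: set[str] = set()
    for pair in sorted(tuple(sorted(p)) for p in ont.equivalence_axioms):
        lines.append(f"{pair[0]}\tequivalent\t{pair[1]}")
        covered.update(pair)
    for child, parent in sorted(ont.subclass_edges):
        lines.append(f"{child}\tis_a\t{parent}")
        covered.update((child, parent))
    for whole, part in sorted(ont.subsume_edges):
        lines.append(f"{whole}\tsubsume\t{part}")
        covered.update((whole, part))
    for name in sorted(ont.classes - covered):
        lines.append(f"{name}\tclass\t{name}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# reasoning


def equivalence_set(ont: SyndromeOntology, name: str) -> set[str]:
    """Reflexive-symmetric-transitive closure of equivalence containing name."""
    group = {name}
    frontier = [name]
    while frontier:
        current = frontier.pop()
        for pair in ont.equivalence_axioms:
            if current in pair:
                for other in pair:
                    if other not in group:
                        group.add(other)
                        frontier.append(other)
    return group


def ancestors(ont: SyndromeOntology, name: str) -> set[str]:
    """All (transitive) superclasses of name, excluding name itself."""
    graph = nx.DiGraph(ont.subclass_edges)
    if name not in graph:
        return set()
    return set(nx.descendants(graph, name))


def subsumed_parts(ont: SyndromeOntology, name: str) -> set[str]:
    """Direct parts of a compound syndrome (no transitive closure)."""
    return {part for whole, part in ont.subsume_edges if whole == name}


def subsumers_of(ont: SyndromeOntology, name: str) -> set[str]:
    """Compound syndromes that directly subsume name."""
    return {whole for whole, part in ont.subsume_edges if part == name}


def effective_symptoms(
    ont: SyndromeOntology,
    table,  # MappingTable; untyped to avoid an import cycle
    name: str,
    *,
    merge_equivalents: bool = False,
    _stack: frozenset[str] = frozenset(),
) -> frozenset[str]:
    """Ontology-closed symptom set of a syndrome.

    The union of (a) the library symptoms of every equivalent name, (b)
    the library symptoms of every superclass (inheritance), and (c) the
    effective symptoms of every subsumed part, recursively (a part may
    itself be a compound).  With ``merge_equivalents`` the subclass and
    subsume edges of equivalent names are also followed; by default
    equivalence contributes symptoms only.
    """
    if name in _stack:
        raise InvalidOntologyError(
            f"subsume cycle detected at {name!r}: {sorted(_stack)}"
        )
    stack = _stack | {name}

    members = equivalence_set(ont, name)
    result: set[str] = set()
    for member in members:
        result |= table.symptoms_of("syndrome", member)

    expand_from = members if merge_equivalents else {name}
    for origin in expand_from:
        for sup in ancestors(ont, origin):
            result |= table.symptoms_of("syndrome", sup)
        for part in subsumed_parts(ont, origin):
            result |= effective_symptoms(
                ont, table, part, merge_equivalents=merge_equivalents, _stack=stack
            )
    return frozenset(result)


def ontology_stats(ont: SyndromeOntology) -> dict[str, int]:
    """Raw axiom counts as parsed (named classes only, no closures)."""
    return {
        "classes": len(ont.classes),
        "subclass_axioms": len(ont.subclass_edges),
        "equivalent_axioms": len(ont.equivalence_axioms),
        "subsume_axioms": len(ont.subsume_edges),
    }
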