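"""Synthetic clinical case tables and ontologies with planted ground truth.

The generator emulates the structure of a curated TCM case database:
every syndrome has a stable symptom signature shared by its cases, each
recorded case drops a few signature symptoms (incomplete observation) and
picks up noise symptoms (co-incidental complaints), and case lengths stay
within the 1–32 range observed in such databases.  On top of the flat
signatures the ontology layer plants equivalence aliases, subclass chains
(child signature extends the parent's) and compound syndromes whose
signature is the union of their parts — exactly the relations the
refinement machinery is supposed to exploit.

``evaluate_recovery`` closes the loop: it measures how much of the
planted truth the extraction pipeline reconstructs from the noisy cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import numpy as np

from .cases import ClinicalCase
from .extract import MappingTable
from .ontology import SyndromeOntology

__all__ = [
    "RecoveryMetrics",
    "SyntheticTruth",
    "evaluate_recovery",
    "generate_cases",
    "generate_truth",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth: signatures, disease assignment, ontology."""

    signatures: dict[str, frozenset[str]]
    disease_map: dict[str, set[str]]  # disease -> syndromes assigned to it
    ontology: SyndromeOntology
    vocabulary: tuple[str, ...]
    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def disease_of(self, syndrome: str) -> str:
        for disease, members in self.disease_map.items():
            if syndrome in members:
                return disease
        raise KeyError(syndrome)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "signatures": {k: sorted(v) for k, v in sorted(self.signatures.items())},
            "disease_map": {k: sorted(v) for k, v in sorted(self.disease_map.items())},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def generate_truth(
    n_syndromes: int = 30,
    n_diseases: int = 5,
    vocab_size: int = 300,
    signature_size: int = 6,
    p_equiv: float = 0.1,
    p_subsume: float = 0.1,
    subclass_depth: int = 1,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant syndrome signatures, a disease assignment and ontology axioms.

    Base signatures are sampled without replacement from a synthetic
    vocabulary.  With probability ``p_subsume`` per base syndrome a
    compound syndrome is added whose signature is the union of two parts;
    with probability ``p_equiv`` an alias class is linked by an
    equivalence axiom.  ``subclass_depth`` > 1 arranges consecutive base
    syndromes into inheritance chains where each child's signature is a
    superset of its parent's.
    """
    if n_syndromes < 1 or n_diseases < 1:
        raise ValueError("counts must be >= 1")
    if signature_size > vocab_size:
        raise ValueError("signature_size cannot exceed vocab_size")
    if subclass_depth < 1:
        raise ValueError("subclass_depth must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = tuple(f"sym{i:04d}" for i in range(vocab_size))
    names = [f"syndrome{i:03d}" for i in range(n_syndromes)]

    signatures: dict[str, frozenset[str]] = {}
    subclass_edges: set[tuple[str, str]] = set()
    chain_extra = max(1, signature_size // 3)
    for idx, name in enumerate(names):
        if subclass_depth > 1 and idx % subclass_depth != 0:
            # continue the chain: child signature extends the parent's
            parent = names[idx - 1]
            pool = [s for s in vocab if s not in signatures[parent]]
            extra = rng.choice(len(pool), size=chain_extra, replace=False)
            signatures[name] = signatures[parent] | {pool[i] for i in extra}
            subclass_edges.add((name, parent))
        else:
            picks = rng.choice(vocab_size, size=signature_size, replace=False)
            signatures[name] = frozenset(vocab[i] for i in picks)

    equivalences: set[frozenset[str]] = set()
    classes: set[str] = set(names)
    for name in names:
        if rng.random() < p_equiv:
            alias = f"{name} alias"
            classes.add(alias)
            equivalences.add(frozenset((name, alias)))

    subsume_edges: set[tuple[str, str]] = set()
    for name in names:
        if rng.random() < p_subsume and n_syndromes >= 2:
            partner = name
            while partner == name:
                partner = names[int(rng.integers(n_syndromes))]
            compound = f"{name}+{partner}"
            if compound in signatures:
                continue
            signatures[compound] = signatures[name] | signatures[partner]
            subsume_edges.add((compound, name))
            subsume_edges.add((compound, partner))
            classes.add(compound)

    diseases = [f"disease{i:02d}" for i in range(n_diseases)]
    disease_map: dict[str, set[str]] = {d: set() for d in diseases}
    for name in sorted(signatures):
        disease_map[diseases[int(rng.integers(n_diseases))]].add(name)

    ontology = SyndromeOntology(
        classes=classes,
        equivalence_axioms=equivalences,
        subclass_edges=subclass_edges,
        subsume_edges=subsume_edges,
    )
    return SyntheticTruth(
        signatures=signatures,
        disease_map=disease_map,
        ontology=ontology,
        vocabulary=vocab,
        seed=seed,
        params={
            "n_syndromes": n_syndromes,
            "n_diseases": n_diseases,
            "vocab_size": vocab_size,
            "signature_size": signature_size,
            "p_equiv": p_equiv,
            "p_subsume": p_subsume,
            "subclass_depth": subclass_depth,
        },
    )


def generate_cases(
    truth: SyntheticTruth,
    cases_per_syndrome: int = 20,
    p_drop: float = 0.05,
    n_extra: float = 3.0,
    length_range: tuple[int, int] = (1, 32),
    seed: int = 0,
) -> list[ClinicalCase]:
    """Sample noisy cases from the planted signatures.

    Each case keeps its syndrome's signature minus independently dropped
    symptoms (probability ``p_drop`` each, at least one always kept),
    plus a Poisson(``n_extra``)-distributed number of noise symptoms from
    the vocabulary; the total length is clamped to ``length_range``.
    """
    if not 0.0 <= p_drop <= 1.0:
        raise ValueError("p_drop must be a probability")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    vocab = truth.vocabulary
    cases: list[ClinicalCase] = []
    for syndrome in sorted(truth.signatures):
        signature = sorted(truth.signatures[syndrome])
        disease = truth.disease_of(syndrome)
        for _ in range(cases_per_syndrome):
            kept = [s for s in signature if rng.random() >= p_drop]
            if not kept:
                kept = [signature[int(rng.integers(len(signature)))]]
            n_noise = int(rng.poisson(n_extra))
            symptoms = list(kept)
            if n_noise:
                picks = rng.choice(len(vocab), size=min(n_noise, len(vocab)), replace=False)
                for i in picks:
                    if vocab[i] not in symptoms:
                        symptoms.append(vocab[i])
            symptoms = symptoms[:hi]  # clamp; lower bound holds since kept >= 1
            cases.append(
                ClinicalCase(disease=disease, syndrome=syndrome, symptoms=tuple(symptoms))
            )
    return cases


@dataclass
class RecoveryMetrics:
    """How well extraction recovered the planted signatures."""

    exact_fraction: float
    mean_jaccard: float
    per_syndrome: dict[str, float] = field(default_factory=dict)


def evaluate_recovery(table: MappingTable, truth: SyntheticTruth) -> RecoveryMetrics:
    """Compare extracted syndrome entries with the planted signatures.

    A syndrome missing from the table counts as Jaccard 0; exact_fraction
    is the share of syndromes whose entry equals its signature.
    """
    per: dict[str, float] = {}
    exact = 0
    for syndrome, signature in sorted(truth.signatures.items()):
        entry = table.get("syndrome", syndrome)
        if entry is None:
            per[syndrome] = 0.0
            continue
        inter = len(entry.symptoms & signature)
        union = len(entry.symptoms | signature)
        per[syndrome] = inter / union if union else 1.0
        if entry.symptoms == signature:
            exact += 1
    n = len(truth.signatures)
    return RecoveryMetrics(
        exact_fraction=exact / n if n else 0.0,
        mean_jaccard=sum(per.values()) / n if n else 0.0,
        per_syndrome=per,
    )
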