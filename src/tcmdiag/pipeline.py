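"""End-to-end fuzzy diagnosis: symptoms in, disease + syndromes out.

The diagnoser ranks the diagnostic library's disease entries and syndrome
entries independently against the normalised input, refines the top
syndrome candidate through the ontology, re-ranks the refined candidates
by effective-symptom similarity, and assembles the combined answer with a
full audit trace.  With an empty ontology the refinement is the identity
and the pipeline reduces exactly to the raw fuzzy ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence, Union

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from .cases import ClinicalCase, normalize_symptom, parse_cases
from .extract import MappingTable, MinimumSymptomSetExtractor
from .ontology import SyndromeOntology, load_ontology, write_ontology_tsv
from .refinement import (
    DecompositionConfig,
    RefinementTrace,
    RelationKind,
    match_relation,
    refine,
)
from .similarity import SimilarityScore, rank_candidates

__all__ = [
    "Diagnosis",
    "OntologyDiagnoser",
    "build_model",
    "diagnose",
    "load_model",
    "save_model",
]

logger = logging.getLogger(__name__)


@dataclass
class Diagnosis:
    """Combined diagnostic answer: a disease plus ranked syndromes.

    ``syndromes`` holds (name, score, provenance) best-first; provenance
    records how each candidate entered the answer (initial ranking, self,
    equivalent, superclass, subsumer or decomposition).
    """

    disease: tuple[str, SimilarityScore] | None
    syndromes: list[tuple[str, SimilarityScore | None, str]]
    trace: RefinementTrace | None = None
    residual_symptoms: set[str] = field(default_factory=set)

    def to_dict(self) -> dict[str, Any]:
        def score_dict(s: SimilarityScore | None) -> dict[str, Any]:
            if s is None:
                return {"sim": 0.0, "exact_count": 0}
            return {"sim": s.sim, "exact_count": s.exact_count}

        out: dict[str, Any] = {
            "disease": None
            if self.disease is None
            else {"name": self.disease[0], **score_dict(self.disease[1])},
            "syndromes": [
                {"name": n, "provenance": p, **score_dict(s)}
                for n, s, p in self.syndromes
            ],
            "residual": sorted(self.residual_symptoms),
        }
        if self.trace is not None:
            out["relation"] = self.trace.relation.value
            if self.trace.decomposition is not None:
                out["combined"] = list(self.trace.decomposition.components)
        return out


class OntologyDiagnoser(BaseEstimator):
    """Fuzzy TCM diagnoser with ontology-based relation refinement.

    ``fit`` extracts the diagnostic library from clinical cases (and
    stores the ontology); ``predict`` returns the top syndrome per query,
    ``diagnose`` the full combined answer with audit trace.

    Parameters
    ----------
    alpha : float, default=1.0
        Fraction of a group's cases a symptom must appear in during
        library extraction.
    t_min : int, default=1
        Lower bound on the extraction threshold.
    fallback_relax : bool, default=True
        Relax the threshold on empty intersections.
    overlap_threshold : float, default=0.3
        Jaccard bound separating a genuine partial overlap from
        disjointness during refinement.
    refine_top_n : int, default=1
        How many top-ranked syndrome candidates are refined.
    smoothing : float, default=0.0
        Additive smoothing of the exact-match multiplier in the
        similarity; 0 keeps the literal formula.
    max_components : int, default=4
        Cap on combined syndromes from partial-overlap decomposition.

    Attributes
    ----------
    table_ : MappingTable
        Extracted diagnostic library.
    ontology_ : SyndromeOntology
        The syndrome knowledge base (possibly empty).
    """

    def __init__(
        self,
        alpha: float = 1.0,
        t_min: int = 1,
        fallback_relax: bool = True,
        overlap_threshold: float = 0.3,
        refine_top_n: int = 1,
        smoothing: float = 0.0,
        max_components: int = 4,
    ) -> None:
        self.alpha = alpha
        self.t_min = t_min
        self.fallback_relax = fallback_relax
        self.overlap_threshold = overlap_threshold
        self.refine_top_n = refine_top_n
        self.smoothing = smoothing
        self.max_components = max_components

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        X: Sequence[ClinicalCase],
        y: None = None,
        ontology: SyndromeOntology | None = None,
    ) -> "OntologyDiagnoser":
        extractor = MinimumSymptomSetExtractor(
            alpha=self.alpha, t_min=self.t_min, fallback_relax=self.fallback_relax
        )
        self.table_ = extractor.fit(X).table_
        if ontology is None:
            ontology = SyndromeOntology()
        self.ontology_ = ontology
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise ValueError("diagnoser is not fitted; call fit() first")

    # -- inference ---------------------------------------------------------

    def _normalize_query(self, symptoms: Iterable[str]) -> list[str]:
        labels: dict[str, None] = {}
        for raw in symptoms:
            try:
                labels.setdefault(normalize_symptom(raw), None)
            except ValueError:
                logger.warning("dropping unusable symptom %r", raw)
        if not labels:
            raise ValueError("no symptom in the query survived normalization")
        return list(labels)

    def diagnose(self, symptoms: Iterable[str]) -> Diagnosis:
        """Full combined diagnosis of a raw symptom list."""
        self._check_fitted()
        if len(self.table_) == 0:
            raise ValueError("mapping table is empty; fit on clinical cases first")
        labels = self._normalize_query(symptoms)

        disease: tuple[str, SimilarityScore] | None = None
        if self.table_.entries("disease"):
            d_entry, d_score = rank_candidates(
                labels, self.table_, "disease", smoothing=self.smoothing
            )[0]
            disease = (d_entry.entity_name, d_score)

        initial = rank_candidates(
            labels, self.table_, "syndrome", smoothing=self.smoothing
        )
        merged: dict[str, tuple[SimilarityScore | None, str]] = {
            e.entity_name: (s, "initial") for e, s in initial
        }

        trace: RefinementTrace | None = None
        decomp_cfg = DecompositionConfig(max_components=self.max_components)
        for entry, _score in initial[: max(1, self.refine_top_n)]:
            rel = match_relation(
                set(labels), entry.symptoms, overlap_threshold=self.overlap_threshold
            )
            t = refine(
                entry.entity_name,
                rel,
                self.ontology_,
                self.table_,
                labels,
                decomposition_config=decomp_cfg,
            )
            if trace is None:
                trace = t
            for cand in t.candidates:
                merged[cand.name] = (cand.score, cand.provenance)

        syndromes = sorted(
            ((name, score, prov) for name, (score, prov) in merged.items()),
            key=lambda nsp: (
                -(nsp[1].sim if nsp[1] else 0.0),
                -(nsp[1].exact_count if nsp[1] else 0),
                nsp[0],
            ),
        )

        residual = self._residual(labels, syndromes, trace)
        logger.info(
            "diagnosis: disease=%s top_syndrome=%s relation=%s residual=%s",
            disease[0] if disease else None,
            syndromes[0][0] if syndromes else None,
            trace.relation.value if trace else None,
            sorted(residual),
        )
        return Diagnosis(
            disease=disease,
            syndromes=syndromes,
            trace=trace,
            residual_symptoms=residual,
        )

    def _residual(
        self,
        labels: Sequence[str],
        syndromes: list[tuple[str, SimilarityScore | None, str]],
        trace: RefinementTrace | None,
    ) -> set[str]:
        from .ontology import effective_symptoms

        if trace is not None and trace.decomposition is not None:
            covered: set[str] = set()
            for comp in trace.decomposition.components:
                covered |= effective_symptoms(self.ontology_, self.table_, comp)
            return {s for s in labels if s not in covered}
        if not syndromes:
            return set(labels)
        top = syndromes[0][0]
        covered = set(effective_symptoms(self.ontology_, self.table_, top))
        if not covered:
            covered = set(self.table_.symptoms_of("syndrome", top))
        return {s for s in labels if s not in covered}

    def predict(self, X: Iterable[Iterable[str]]) -> np.ndarray:
        """Top syndrome name per query (sklearn-style batch interface)."""
        self._check_fitted()
        return np.asarray(
            [self.diagnose(q).syndromes[0][0] for q in X], dtype=object
        )


def diagnose(
    symptoms: Iterable[str],
    table: MappingTable,
    ontology: SyndromeOntology | None = None,
    **params: Any,
) -> Diagnosis:
    """Functional wrapper: diagnose with a pre-built table and ontology."""
    model = OntologyDiagnoser(**params)
    model.table_ = table
    model.ontology_ = ontology if ontology is not None else SyndromeOntology()
    return model.diagnose(symptoms)


# ---------------------------------------------------------------------------
# model bundles


def build_model(
    cases_path: Union[str, Path],
    ontology_path: Union[str, Path, None] = None,
    config: dict[str, Any] | None = None,
) -> OntologyDiagnoser:
    """Parse a case table (and optionally an ontology) into a fitted model.

    A missing ontology degrades gracefully: refinement becomes the
    identity and a warning is emitted.
    """
    cases = parse_cases(cases_path)
    ontology: SyndromeOntology | None = None
    if ontology_path is not None and Path(ontology_path).exists():
        ontology = load_ontology(Path(ontology_path))
    elif ontology_path is not None:
        warnings.warn(
            f"ontology file {ontology_path} not found; refinement will be "
            "the identity",
            stacklevel=2,
        )
    model = OntologyDiagnoser(**(config or {}))
    return model.fit(cases, ontology=ontology)


def save_model(model: OntologyDiagnoser, directory: Union[str, Path]) -> Path:
    """Write a fitted model to a directory (table.json, ontology.tsv, config.yaml)."""
    model._check_fitted()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.table_.to_json(directory / "table.json")
    write_ontology_tsv(model.ontology_, directory / "ontology.tsv")
    (directory / "config.yaml").write_text(
        yaml.safe_dump(model.get_params()), encoding="utf-8"
    )
    return directory


def load_model(directory: Union[str, Path]) -> OntologyDiagnoser:
    """Load a model bundle saved by :func:`save_model`."""
    directory = Path(directory)
    params = yaml.safe_load((directory / "config.yaml").read_text(encoding="utf-8"))
    model = OntologyDiagnoser(**params)
    model.table_ = MappingTable.from_json(directory / "table.json")
    ontology_file = directory / "ontology.tsv"
    text = ontology_file.read_text(encoding="utf-8")
    model.ontology_ = load_ontology(text) if text.strip() else SyndromeOntology()
    return model
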