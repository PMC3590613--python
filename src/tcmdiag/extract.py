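"""Diagnostic-library extraction by t-threshold adaptive set intersection.

Cases sharing a syndrome (or a disease) are reduced to a minimum symptom
set: the symptoms present in at least t of the k contributing cases.  With
t = k this is ordinary multi-set intersection; lowering t tolerates noisy
and incomplete records.  The sorted-sequence path uses the adaptive
intersection scheme (galloping — doubling then binary — search, cycling
through the sets), falling back to a plain linear merge when every set is
small.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from sklearn.base import BaseEstimator

from .cases import ClinicalCase

__all__ = [
    "ThresholdConfig",
    "MappingEntry",
    "MappingTable",
    "MinimumSymptomSetExtractor",
    "adaptive_sorted_intersect",
    "build_mapping_table",
    "choose_threshold",
    "threshold_intersect",
]

#: sets shorter than this are intersected by linear merge instead of galloping
SMALL_SET_CUTOFF = 16


@dataclass(frozen=True)
class ThresholdConfig:
    """How the occurrence threshold t is derived from the group size k.

    Parameters
    ----------
    t_fraction
        Fraction alpha in (0, 1] of the k sets an element must appear in;
        alpha = 1 demands full intersection.
    t_min
        Lower bound on t (>= 1).
    fallback_relax
        If the thresholded intersection comes out empty, decrement t until
        it is non-empty (or t = 1); keeps every library entry non-empty on
        noisy groups.
    """

    t_fraction: float = 1.0
    t_min: int = 1
    fallback_relax: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.t_fraction <= 1.0:
            raise ValueError(f"t_fraction must be in (0, 1], got {self.t_fraction}")
        if self.t_min < 1:
            raise ValueError(f"t_min must be >= 1, got {self.t_min}")


@dataclass(frozen=True)
class MappingEntry:
    """One diagnostic-library row D ~ S: an entity and its minimum symptom set."""

    entity_kind: str  # "disease" or "syndrome"
    entity_name: str
    symptoms: frozenset[str]
    support: int  # number of contributing cases (k)

    def __post_init__(self) -> None:
        if self.entity_kind not in ("disease", "syndrome"):
            raise ValueError(f"unknown entity kind {self.entity_kind!r}")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def sorted_symptoms(self) -> tuple[str, ...]:
        return tuple(sorted(self.symptoms))


class MappingTable:
    """The diagnostic library: mapping entries keyed by (kind, name).

    Holds both the disease->symptoms and the syndrome->symptoms relations
    extracted from the case table.
    """

    def __init__(self, entries: Iterable[MappingEntry] = ()) -> None:
        self._entries: dict[tuple[str, str], MappingEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: MappingEntry) -> None:
        key = (entry.entity_kind, entry.entity_name)
        if key in self._entries:
            raise ValueError(f"duplicate mapping entry for {key}")
        self._entries[key] = entry

    def get(self, kind: str, name: str) -> MappingEntry | None:
        return self._entries.get((kind, name))

    def symptoms_of(self, kind: str, name: str) -> frozenset[str]:
        entry = self.get(kind, name)
        return entry.symptoms if entry is not None else frozenset()

    def entries(self, kind: str | None = None) -> list[MappingEntry]:
        items = sorted(self._entries.items())
        return [e for (k, _), e in items if kind is None or k == kind]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MappingTable):
            return NotImplemented
        return self._entries == other._entries

    # -- serialisation -----------------------------------------------------

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = [
            {
                "kind": e.entity_kind,
                "name": e.entity_name,
                "symptoms": list(e.sorted_symptoms),
                "support": e.support,
            }
            for e in self.entries()
        ]
        text = json.dumps(payload, indent=2, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "MappingTable":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        payload = json.loads(text)
        return cls(
            MappingEntry(
                entity_kind=item["kind"],
                entity_name=item["name"],
                symptoms=frozenset(item["symptoms"]),
                support=item["support"],
            )
            for item in payload
        )

    def to_tsv(self, path: Union[str, Path, None] = None) -> str:
        """Two-column view: ``kind:name<TAB>comma-joined sorted symptoms``."""
        lines = [
            f"{e.entity_kind}:{e.entity_name}\t{','.join(e.sorted_symptoms)}"
            for e in self.entries()
        ]
        text = "\n".join(lines) + ("\n" if lines else "")
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


# ---------------------------------------------------------------------------
# intersection primitives


def threshold_intersect(sets: Sequence[Iterable[str]], t: int) -> list[str]:
    """Elements occurring in at least t of the k input sets, sorted.

    The occurrence-counting formulation of the t-threshold problem; each
    input collection contributes each distinct element once.
    """
    k = len(sets)
    if k < 1:
        raise ValueError("need at least one input set")
    if not 1 <= t <= k:
        raise ValueError(f"threshold t={t} out of range for k={k} sets")
    counts: Counter[str] = Counter()
    for s in sets:
        counts.update(set(s))
    return sorted(e for e, c in counts.items() if c >= t)


def _gallop(seq: Sequence[str], lo: int, target: str) -> int:
    """First index >= lo whose element is >= target, by doubling then bisect."""
    n = len(seq)
    if lo >= n or seq[lo] >= target:
        return lo
    step = 1
    hi = lo + 1
    while hi < n and seq[hi] < target:
        lo = hi
        step <<= 1
        hi = lo + step
    return bisect_left(seq, target, lo + 1, min(hi + 1, n))


def _check_sorted(seqs: Sequence[Sequence[str]]) -> None:
    for i, s in enumerate(seqs):
        for a, b in zip(s, s[1:]):
            if not a < b:
                raise ValueError(
                    f"input sequence {i} is not strictly increasing at {a!r}, {b!r}"
                )


def _linear_merge_intersect(seqs: Sequence[Sequence[str]]) -> list[str]:
    out = list(seqs[0])
    for s in seqs[1:]:
        it = set(s)
        out = [e for e in out if e in it]
    return out


def adaptive_sorted_intersect(
    seqs: Sequence[Sequence[str]], small_cutoff: int = SMALL_SET_CUTOFF
) -> list[str]:
    """Full intersection of k strictly-increasing sequences, adaptively.

    Cycles through the sets with a candidate ("eliminator") element,
    locating it in the next set by galloping search; any overshoot becomes
    the new candidate.  The work done is proportional to the shortest
    certificate of the result, not the input size.  When every input is
    shorter than ``small_cutoff`` the doubling search is skipped in favour
    of a linear merge, which is cheaper on tiny sets.

    Inputs must be strictly increasing; violations raise ``ValueError``.
    """
    if len(seqs) < 1:
        raise ValueError("need at least one input sequence")
    _check_sorted(seqs)
    if len(seqs) == 1:
        return list(seqs[0])
    if any(len(s) == 0 for s in seqs):
        return []
    if all(len(s) < small_cutoff for s in seqs):
        return _linear_merge_intersect(seqs)

    k = len(seqs)
    pos = [0] * k
    out: list[str] = []
    candidate = seqs[0][0]
    matched = 1
    j = 1
    while True:
        idx = _gallop(seqs[j], pos[j], candidate)
        if idx == len(seqs[j]):
            break
        if seqs[j][idx] == candidate:
            pos[j] = idx
            matched += 1
            if matched == k:
                out.append(candidate)
                pos[j] = idx + 1
                if pos[j] == len(seqs[j]):
                    break
                candidate = seqs[j][pos[j]]
                matched = 1
        else:
            pos[j] = idx
            candidate = seqs[j][idx]
            matched = 1
        j = (j + 1) % k
    return out


def choose_threshold(k: int, config: ThresholdConfig = ThresholdConfig()) -> int:
    """Derive t from the group size: t = min(k, max(t_min, ceil(alpha*k)))."""
    if k < 1:
        raise ValueError("group size k must be >= 1")
    return min(k, max(config.t_min, math.ceil(config.t_fraction * k)))


# ---------------------------------------------------------------------------
# library construction


def _extract_group(
    symptom_sets: list[frozenset[str]], config: ThresholdConfig
) -> frozenset[str]:
    k = len(symptom_sets)
    t = choose_threshold(k, config)
    result = threshold_intersect(symptom_sets, t)
    while not result and config.fallback_relax and t > 1:
        t -= 1
        result = threshold_intersect(symptom_sets, t)
    return frozenset(result)


class MinimumSymptomSetExtractor(BaseEstimator):
    """Estimator that learns the diagnostic library from clinical cases.

    ``fit`` groups the cases by syndrome name and, independently, by
    disease name, and reduces each group of k symptom sets to its
    t-threshold intersection (t from ``choose_threshold``); empty results
    are relaxed by decrementing t when ``fallback_relax`` is on.

    Parameters
    ----------
    alpha : float, default=1.0
        Fraction of a group's cases a symptom must appear in.
    t_min : int, default=1
        Lower bound on the derived threshold.
    fallback_relax : bool, default=True
        Relax t on empty intersections so every entry stays non-empty.

    Attributes
    ----------
    table_ : MappingTable
        The extracted diagnostic library (disease and syndrome entries).
    n_cases_ : int
        Number of cases seen during fit.
    """

    def __init__(
        self, alpha: float = 1.0, t_min: int = 1, fallback_relax: bool = True
    ) -> None:
        self.alpha = alpha
        self.t_min = t_min
        self.fallback_relax = fallback_relax

    def _config(self) -> ThresholdConfig:
        return ThresholdConfig(
            t_fraction=self.alpha, t_min=self.t_min, fallback_relax=self.fallback_relax
        )

    def fit(self, X: Sequence[ClinicalCase], y: None = None) -> "MinimumSymptomSetExtractor":
        cases = list(X)
        if not cases:
            raise ValueError("cannot build a mapping table from zero cases")
        config = self._config()
        by_syndrome: dict[str, list[frozenset[str]]] = defaultdict(list)
        by_disease: dict[str, list[frozenset[str]]] = defaultdict(list)
        for case in cases:
            by_syndrome[case.syndrome].append(case.symptom_set)
            by_disease[case.disease].append(case.symptom_set)
        table = MappingTable()
        for kind, groups in (("disease", by_disease), ("syndrome", by_syndrome)):
            for name in sorted(groups):
                sets = groups[name]
                table.add(
                    MappingEntry(
                        entity_kind=kind,
                        entity_name=name,
                        symptoms=_extract_group(sets, config),
                        support=len(sets),
                    )
                )
        self.table_ = table
        self.n_cases_ = len(cases)
        return self


def build_mapping_table(
    cases: Sequence[ClinicalCase], config: ThresholdConfig = ThresholdConfig()
) -> MappingTable:
    """Build the diagnostic library from cases (functional wrapper)."""
    est = MinimumSymptomSetExtractor(
        alpha=config.t_fraction,
        t_min=config.t_min,
        fallback_relax=config.fallback_relax,
    )
    return est.fit(cases).table_
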