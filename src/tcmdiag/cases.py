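"""Reading, normalising and validating three-column clinical case tables.

A clinical case table has one row per observed case with columns
``disease``, ``syndrome`` and ``symptoms``, where the symptoms cell is an
internally delimited list of free-text symptom descriptions.  Symptom
labels are canonicalised (case-folded, whitespace-collapsed) so that equal
descriptions compare equal as set elements.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "CaseDialect",
    "CaseParseError",
    "ClinicalCase",
    "case_length_histogram",
    "normalize_symptom",
    "parse_cases",
    "write_cases",
]

REQUIRED_COLUMNS = ("disease", "syndrome", "symptoms")


class CaseParseError(ValueError):
    """A case table row or header violates the three-column contract."""


@dataclass(frozen=True)
class CaseDialect:
    """Serialisation dialect of a case table.

    The outer table delimiter and the inner delimiter of the symptoms cell
    are both configurable because the source databases this emulates never
    fixed a serialisation.
    """

    delimiter: str = ","
    symptom_separator: str = ","

    def __post_init__(self) -> None:
        if self.symptom_separator not in {",", ";", "|"}:
            raise ValueError(
                f"unsupported symptom separator {self.symptom_separator!r}; "
                "use ',', ';' or '|'"
            )


@dataclass(frozen=True)
class ClinicalCase:
    """One database row: a disease C, a syndrome Q and its symptom set S.

    ``symptoms`` is an ordered, duplicate-free tuple of normalised labels;
    the order preserves first occurrence in the source row.
    """

    disease: str
    syndrome: str
    symptoms: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.symptoms:
            raise ValueError("a clinical case requires at least one symptom")
        if len(set(self.symptoms)) != len(self.symptoms):
            raise ValueError(f"duplicate symptom labels in case: {self.symptoms}")

    @property
    def symptom_set(self) -> frozenset[str]:
        return frozenset(self.symptoms)

    def __len__(self) -> int:
        return len(self.symptoms)


def normalize_symptom(raw: str) -> str:
    """Canonicalise a raw symptom description into a comparable label.

    Trims, case-folds and collapses internal whitespace; no stemming or
    translation is attempted, matching is purely textual downstream.

    Raises
    ------
    ValueError
        If nothing remains after normalisation.
    """
    label = " ".join(str(raw).split()).casefold()
    if not label:
        raise ValueError(f"symptom {raw!r} is empty after normalization")
    return label


def _parse_symptom_cell(cell: str, sep: str) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for token in str(cell).split(sep):
        token = token.strip()
        if not token:
            continue
        seen.setdefault(normalize_symptom(token), None)
    return tuple(seen)


def parse_cases(
    source: Union[str, Path, io.TextIOBase],
    dialect: CaseDialect = CaseDialect(),
) -> list[ClinicalCase]:
    """Parse a delimited case table into a list of :class:`ClinicalCase`.

    Parameters
    ----------
    source
        Path to a delimited file, or an open text buffer.
    dialect
        Outer/inner delimiter configuration.

    Rows whose symptom cell is empty after normalisation are skipped with
    a warning; rows missing the disease or syndrome value raise
    :class:`CaseParseError` with the offending line number.
    """
    try:
        frame = pd.read_csv(
            source, sep=dialect.delimiter, dtype=str, skipinitialspace=True
        )
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CaseParseError(f"case table is missing column(s) {missing}")

    cases: list[ClinicalCase] = []
    skipped = 0
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header occupies line 1
        disease = row["disease"]
        syndrome = row["syndrome"]
        if pd.isna(disease) or pd.isna(syndrome):
            raise CaseParseError(f"line {line}: missing disease or syndrome value")
        symptoms_cell = "" if pd.isna(row["symptoms"]) else row["symptoms"]
        symptoms = _parse_symptom_cell(symptoms_cell, dialect.symptom_separator)
        if not symptoms:
            skipped += 1
            warnings.warn(
                f"line {line}: empty symptom list, row skipped", stacklevel=2
            )
            continue
        cases.append(
            ClinicalCase(
                disease=str(disease).strip(),
                syndrome=str(syndrome).strip(),
                symptoms=symptoms,
            )
        )
    return cases


def write_cases(
    cases: Iterable[ClinicalCase],
    target: Union[str, Path, io.TextIOBase],
    dialect: CaseDialect = CaseDialect(),
) -> None:
    """Serialise cases back to the three-column table format."""
    frame = pd.DataFrame(
        {
            "disease": [c.disease for c in cases],
            "syndrome": [c.syndrome for c in cases],
            "symptoms": [
                dialect.symptom_separator.join(c.symptoms) for c in cases
            ],
        },
        columns=list(REQUIRED_COLUMNS),
    )
    frame.to_csv(target, sep=dialect.delimiter, index=False)


def case_length_histogram(cases: Iterable[ClinicalCase]) -> dict[int, int]:
    """Histogram of case lengths: symptom count -> number of cases."""
    return dict(Counter(len(c) for c in cases))
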