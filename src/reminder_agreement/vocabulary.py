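"""Fixture terminology: named concept sets loaded from a versioned CSV.

Rule predicates never test raw codes; they test membership in a named
:class:`ConceptSet`.  The shipped vocabulary contains the three codes the
source engines are known to have disagreed on in the wild — LOINC 8480-6
("Systolic Blood Pressure"), LOINC 8459-0 ("Systolic Blood Pressure -
Sitting") and SNOMED CT 194828000 (Angina) — plus project-invented
placeholder codes for every other concept (flagged as synthetic in their
display text).  Unknown systems/codes are legal in records and simply never
match any set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, FrozenSet, Iterable

from .records import ConceptCode

__all__ = ["ConceptSet", "concept_set", "load_vocabulary", "union"]


@dataclass(frozen=True)
class ConceptSet:
    """A named collection of concept codes with exact (system, code) lookup."""

    name: str
    members: FrozenSet[ConceptCode] = field(default_factory=frozenset)

    def __contains__(self, concept: ConceptCode) -> bool:
        return concept in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __or__(self, other: "ConceptSet") -> "ConceptSet":
        return ConceptSet(f"{self.name}|{other.name}", self.members | other.members)


def union(name: str, sets: Iterable[ConceptSet]) -> ConceptSet:
    members: frozenset[ConceptCode] = frozenset()
    for s in sets:
        members |= s.members
    return ConceptSet(name, members)


@lru_cache(maxsize=1)
def load_vocabulary() -> Dict[str, ConceptSet]:
    """Load the packaged vocabulary CSV into a name -> ConceptSet map."""
    text = resources.files("reminder_agreement.data").joinpath("vocabulary.csv").read_text("utf-8")
    grouped: Dict[str, set[ConceptCode]] = {}
    for row in csv.DictReader(text.splitlines()):
        code = ConceptCode(system=row["system"], code=row["code"], display=row["display"] or None)
        grouped.setdefault(row["set_name"], set()).add(code)
    return {name: ConceptSet(name, frozenset(codes)) for name, codes in grouped.items()}


def concept_set(name: str) -> ConceptSet:
    """Look up a named set from the packaged vocabulary."""
    vocab = load_vocabulary()
    try:
        return vocab[name]
    except KeyError:
        raise KeyError(f"unknown concept set {name!r}; known: {sorted(vocab)}") from None
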