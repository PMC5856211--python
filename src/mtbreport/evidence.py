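"""The six-level evidence system for variant–drug associations.

Each association is stratified along two axes: cancer type (A = evidence in
the same cancer type as the patient, B = evidence in any other cancer type)
and strength of clinical evidence (1 = supported by drug approval
organizations or clinical guidelines; 2 = clinical evidence, with late
trials ranked above early trials above case reports — sub-ranks 2a/2b/2c;
3 = preclinical evidence).  The display-level ranking is
A1 > B1 > A2 > B2 > A3 > B3, with the 2a > 2b > 2c sub-ranks nested inside
each level-2 block.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

from mtbreport.knowledgebase import Tier
from mtbreport.matching import MatchRecord

_STRENGTHS = ("1", "2a", "2b", "2c", "3")

# Full fine-grained order, best first.
LEVEL_ORDER = (
    "A1", "B1",
    "A2a", "A2b", "A2c",
    "B2a", "B2b", "B2c",
    "A3", "B3",
)

COARSE_LEVELS = ("A1", "B1", "A2", "B2", "A3", "B3")

_TIER_TO_STRENGTH = {
    Tier.approved: "1",
    Tier.late_trial: "2a",
    Tier.early_trial: "2b",
    Tier.case_report: "2c",
    Tier.preclinical: "3",
}


@total_ordering
@dataclass(frozen=True)
class EvidenceLevel:
    """An (axis, strength) pair; ordered best-first per LEVEL_ORDER."""

    axis: str      # "A" | "B"
    strength: str  # "1" | "2a" | "2b" | "2c" | "3"

    def __post_init__(self) -> None:
        if self.axis not in ("A", "B"):
            raise ValueError(f"axis must be A or B, got {self.axis!r}")
        if self.strength not in _STRENGTHS:
            raise ValueError(f"strength must be one of {_STRENGTHS}, got {self.strength!r}")

    @property
    def display(self) -> str:
        return f"{self.axis}{self.strength}"

    @property
    def coarse(self) -> str:
        """Six-level display form: sub-ranks 2a/2b/2c collapse to 2."""
        return f"{self.axis}{self.strength[0]}"

    @property
    def rank(self) -> int:
        return LEVEL_ORDER.index(self.display)

    def __lt__(self, other: "EvidenceLevel") -> bool:
        return self.rank < other.rank

    @classmethod
    def from_display(cls, text: str) -> "EvidenceLevel":
        text = text.strip()
        if text not in LEVEL_ORDER:
            raise ValueError(f"unknown evidence level {text!r}")
        return cls(axis=text[0], strength=text[1:])


def assign_level(match: MatchRecord, patient_cancer_type: str) -> EvidenceLevel | None:
    """Assign an evidence level to a match, or None for unranked entries.

    Axis A iff the entry's (harmonized) disease equals the patient's
    (harmonized) cancer type — exact, case-insensitive label equality, no
    ontology ancestry.  Strength follows the entry's evidence tier.  TARGET
    entries carry no evidence levels and return None (reported gene-level
    only).
    """
    entry = match.entry
    if entry.tier is Tier.unranked:
        return None
    same = entry.disease.strip().lower() == patient_cancer_type.strip().lower()
    axis = "A" if same else "B"
    return EvidenceLevel(axis=axis, strength=_TIER_TO_STRENGTH[entry.tier])


def compare_levels(x: EvidenceLevel | None, y: EvidenceLevel | None) -> int:
    """Three-way comparison: -1 if x ranks better (earlier) than y, 0 if
    equal, +1 otherwise.  ``None`` (unranked) sorts after B3."""
    rx = x.rank if x is not None else len(LEVEL_ORDER)
    ry = y.rank if y is not None else len(LEVEL_ORDER)
    return (rx > ry) - (rx < ry)


def cumulative_level_sets() -> list[set[str]]:
    """The six nested level prefixes used for cumulative coverage:
    [{A1}, {A1,B1}, ..., all six coarse levels]."""
    sets: list[set[str]] = []
    acc: set[str] = set()
    for level in COARSE_LEVELS:
        acc = acc | {level}
        sets.append(set(acc))
    return sets
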