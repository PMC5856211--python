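"""Matching patient alterations to knowledge-base entries.

The matcher follows a narrowing-down procedure: patient variants are first
queried at gene level; for each altered gene the variant type is matched to
the entry's variant specifier; for SNVs the protein change is further
checked.  Variants that fail the central path are of unknown significance and
two repurposing side arms apply:

* hotspot repurposing — an unknown-significance SNV is matched to hotspot
  (exact protein change) entries of the same gene provided *all* associations
  between that gene and the drug in the knowledge base point in the same
  direction (always response, or always resistance);
* loss-of-function repurposing — a stopgain (or frameshift/splice) mutation
  is matched to the gene's copy-number-loss / loss-of-function entries.

Fusions are never repurposed into missense matches, and repurposing applies
to SNVs/indels only — this deliberately trades sensitivity for a low false
positive rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Union

from mtbreport.knowledgebase import (
    Association,
    KnowledgeBaseEntry,
    Tier,
    VariantKind,
)
from mtbreport.patient_io import CNV, CNVStatus, Fusion, PatientProfile, SNV, SNVClass

logger = logging.getLogger(__name__)

PatientVariant = Union[SNV, CNV, Fusion, str]  # str = wild-type gene symbol


class MatchMode(str, Enum):
    exact_change = "exact_change"
    any_missense = "any_missense"
    type_match = "type_match"
    repurposed_hotspot = "repurposed_hotspot"
    repurposed_lof = "repurposed_lof"
    wild_type = "wild_type"


# Strongest first; when one variant matches one entry through several modes
# only the strongest is kept.
_MODE_STRENGTH = {
    MatchMode.exact_change: 0,
    MatchMode.any_missense: 1,
    MatchMode.type_match: 2,
    MatchMode.repurposed_hotspot: 3,
    MatchMode.repurposed_lof: 4,
    MatchMode.wild_type: 5,
}

_REPURPOSED = (MatchMode.repurposed_hotspot, MatchMode.repurposed_lof)

# SNV classes that take the loss-of-function side arm.  Splice sites are
# treated as inactivating by convention and flagged in the report.
_LOF_CLASSES = (SNVClass.stopgain, SNVClass.frameshift_indel, SNVClass.splice)

# SNV classes eligible for hotspot repurposing when the protein change is not
# in the database (stoploss is treated like missense here).
_HOTSPOT_ELIGIBLE = (
    SNVClass.missense,
    SNVClass.inframe_indel,
    SNVClass.stoploss,
    SNVClass.other,
)


@dataclass(frozen=True)
class MatchRecord:
    """One patient variant joined to one knowledge-base entry."""

    patient_variant: PatientVariant
    entry: KnowledgeBaseEntry
    match_mode: MatchMode
    known_significance: bool

    def __post_init__(self) -> None:
        if (self.match_mode in _REPURPOSED) == self.known_significance:
            raise ValueError(
                "known_significance must be false exactly for repurposed matches"
            )

    @property
    def gene(self) -> str:
        return self.entry.gene

    @property
    def variant_display(self) -> str:
        v = self.patient_variant
        if isinstance(v, SNV):
            change = f" ({v.protein_change})" if v.protein_change else ""
            return f"{v.gene} {v.classification.value}{change}"
        if isinstance(v, CNV):
            return f"{v.gene} {v.status.value}"
        if isinstance(v, Fusion):
            return f"{v.gene5p}-{v.gene3p} fusion"
        return f"{v} wild type"

    @property
    def sort_key(self) -> tuple:
        return (self.gene, self.variant_display, self.match_mode.value, self.entry.sort_key)


def direction_consistent(gene: str, drug: str, kb: Sequence[KnowledgeBaseEntry]) -> bool:
    """True iff every (gene, drug) entry in the merged kb shares one
    association direction; vacuously false when no such entry exists."""
    gene = gene.upper()
    directions = {
        e.association for e in kb if e.gene == gene and drug in e.drugs
    }
    return len(directions) == 1


def _keep_strongest(records: Iterable[MatchRecord]) -> list[MatchRecord]:
    best: dict[tuple, MatchRecord] = {}
    for r in records:
        key = (r.patient_variant, r.entry)
        old = best.get(key)
        if old is None or _MODE_STRENGTH[r.match_mode] < _MODE_STRENGTH[old.match_mode]:
            best[key] = r
    return sorted(best.values(), key=lambda r: r.sort_key)


def match_snv(snv: SNV, kb: Sequence[KnowledgeBaseEntry]) -> list[MatchRecord]:
    """Match one SNV/indel against the knowledge base.

    Silent variants never match.  See the module docstring for the central
    path vs repurposing side arms.
    """
    if snv.is_silent:
        return []
    records: list[MatchRecord] = []
    for entry in kb:
        if entry.gene != snv.gene:
            continue
        mode = _snv_mode(snv, entry, kb)
        if mode is None:
            continue
        records.append(
            MatchRecord(
                patient_variant=snv,
                entry=entry,
                match_mode=mode,
                known_significance=mode not in _REPURPOSED,
            )
        )
    return _keep_strongest(records)


def _snv_mode(snv: SNV, entry: KnowledgeBaseEntry, kb: Sequence[KnowledgeBaseEntry]) -> MatchMode | None:
    kind = entry.variant.kind
    if kind is VariantKind.exact_protein_change:
        if snv.protein_change and snv.protein_change in entry.variant.descriptors:
            return MatchMode.exact_change
        if snv.classification in _HOTSPOT_ELIGIBLE and all(
            direction_consistent(entry.gene, drug, kb) for drug in entry.drugs
        ):
            return MatchMode.repurposed_hotspot
        return None
    if kind is VariantKind.any_missense:
        return MatchMode.any_missense if snv.classification is SNVClass.missense else None
    if kind in (VariantKind.any_inactivating, VariantKind.deletion):
        if snv.classification in _LOF_CLASSES:
            return MatchMode.repurposed_lof
        if entry.tier is Tier.unranked:
            return MatchMode.type_match  # gene-level hit, variant-unspecific source
        return None
    if kind in (VariantKind.any_activating,):
        # Variant-unspecific sources (TARGET) are hit at gene level by any
        # non-silent mutation; ranked sources require variant evidence.
        return MatchMode.type_match if entry.tier is Tier.unranked else None
    return None


def match_cnv(cnv: CNV, kb: Sequence[KnowledgeBaseEntry]) -> list[MatchRecord]:
    """Match one copy-number call.

    Only high-level events qualify: +2 matches amplification /
    gain-of-function entries, -2 matches deletion / loss-of-function entries.
    CNVs never match hotspot or any-missense entries and are never
    repurposed.
    """
    status = cnv.status
    if status is CNVStatus.not_actionable:
        return []
    wanted = (
        (VariantKind.amplification, VariantKind.any_activating)
        if status is CNVStatus.high_amplification
        else (VariantKind.deletion, VariantKind.any_inactivating)
    )
    records = [
        MatchRecord(cnv, entry, MatchMode.type_match, True)
        for entry in kb
        if entry.gene == cnv.gene and entry.variant.kind in wanted
    ]
    return _keep_strongest(records)


def match_fusion(fusion: Fusion, kb: Sequence[KnowledgeBaseEntry]) -> list[MatchRecord]:
    """Match a gene fusion: a fusion entry on either partner gene matches if
    its descriptor is ``any`` or names the other partner."""
    records: list[MatchRecord] = []
    for entry in kb:
        if entry.variant.kind is not VariantKind.fusion:
            continue
        for this, other in ((fusion.gene5p, fusion.gene3p), (fusion.gene3p, fusion.gene5p)):
            if entry.gene != this:
                continue
            descriptors = entry.variant.descriptors
            if "any" in descriptors or other in descriptors:
                records.append(MatchRecord(fusion, entry, MatchMode.type_match, True))
                break
    return _keep_strongest(records)


def match_wildtype(profile: PatientProfile, kb: Sequence[KnowledgeBaseEntry]) -> list[MatchRecord]:
    """Match wild-type biomarkers (e.g. KRAS wild type -> anti-EGFR response
    in colorectal cancer): entries conditioned on the *absence* of any
    alteration in a gene."""
    altered = profile.altered_genes()
    records = [
        MatchRecord(entry.gene, entry, MatchMode.wild_type, True)
        for entry in kb
        if entry.variant.kind is VariantKind.wild_type and entry.gene not in altered
    ]
    return _keep_strongest(records)


def match_profile(profile: PatientProfile, kb: Sequence[KnowledgeBaseEntry]) -> list[MatchRecord]:
    """Run the full flowchart over one patient profile.

    Concatenates SNV, CNV, fusion and wild-type matching, deduplicated on
    (variant, entry) keeping the strongest mode, in deterministic order.
    """
    records: list[MatchRecord] = []
    for snv in profile.snvs:
        records.extend(match_snv(snv, kb))
    for cnv in profile.cnvs:
        records.extend(match_cnv(cnv, kb))
    for fusion in profile.fusions:
        records.extend(match_fusion(fusion, kb))
    records.extend(match_wildtype(profile, kb))
    return _keep_strongest(records)
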