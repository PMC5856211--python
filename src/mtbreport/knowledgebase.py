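"""Harmonization of predictive-biomarker knowledge bases.

Three public databases of actionable somatic variants — GDKD (Gene Drug
Knowledge Database), CIViC (Clinical Interpretation of Variants in Cancer) and
TARGET (Tumor Alterations Relevant for Genomics-driven Therapy) — annotate
gene–drug predictive associations in different dialects.  This module parses
each dialect into a single harmonized record type
(:class:`KnowledgeBaseEntry`), maps the per-source association and evidence
vocabularies onto a common one, and aggregates equivalent entries.

Two annotation styles coexist in these databases and are kept distinct in the
harmonized model: hotspot annotations (a specific protein change, CNV or
fusion with well-known therapeutic implications, e.g. BRAF V600E) and
variant-class annotations ("any missense mutation", "any loss/gain of
function"), common for genes studied as a whole in trials and preclinical
work.  The distinction drives the downstream matching flowchart.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class Source(str, Enum):
    """Provenance of a harmonized entry."""

    GDKD = "GDKD"
    CIVIC = "CIViC"
    TARGET = "TARGET"
    EXPERT = "EXPERT"


class VariantKind(str, Enum):
    """How a database specifies the actionable variant."""

    exact_protein_change = "exact_protein_change"
    any_missense = "any_missense"
    any_inactivating = "any_inactivating"
    any_activating = "any_activating"
    amplification = "amplification"
    deletion = "deletion"
    fusion = "fusion"
    wild_type = "wild_type"


class Association(str, Enum):
    response = "response"
    resistance = "resistance"


class Tier(str, Enum):
    """Harmonized evidence strength of an entry.

    ``unranked`` is reserved for TARGET, which provides no evidence levels
    and no variant specifics; such entries are reported gene-level only and
    never enter the A1–B3 table.
    """

    approved = "approved"
    late_trial = "late_trial"
    early_trial = "early_trial"
    case_report = "case_report"
    preclinical = "preclinical"
    unranked = "unranked"


# Three-letter to one-letter amino-acid codes (incl. Ter/Stop -> X, the
# convention used for stopgain descriptors such as R505X).
_AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "X", "Stop": "X",
}
_AA3_RE = re.compile("|".join(_AA_3TO1), flags=re.IGNORECASE)


def normalize_protein_change(text: str) -> str:
    """Normalize a short protein-change descriptor.

    Strips the ``p.`` prefix, converts three-letter amino-acid codes to
    one-letter, removes whitespace (databases and papers print artifacts like
    ``T790 M``) and uppercases.  ``*`` (stop) becomes ``X``.

    >>> normalize_protein_change("p.Val600Glu")
    'V600E'
    >>> normalize_protein_change("T790 M")
    'T790M'
    """
    s = text.strip()
    if s.lower().startswith("p."):
        s = s[2:]
    s = _AA3_RE.sub(lambda m: _AA_3TO1[m.group(0).title()], s)
    s = re.sub(r"\s+", "", s)
    s = s.replace("*", "X")
    return s.upper()


@dataclass(frozen=True, order=True)
class VariantSpecifier:
    """The variant side of a knowledge-base entry.

    ``descriptors`` is non-empty only for ``exact_protein_change`` (one or
    more normalized protein changes, e.g. ``("V600E", "V600K")``) and for
    ``fusion`` (the partner gene symbol, or ``"any"``).
    """

    kind: VariantKind
    descriptors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        needs = self.kind in (VariantKind.exact_protein_change, VariantKind.fusion)
        if needs and not self.descriptors:
            raise ValueError(f"{self.kind.value} specifier requires descriptors")
        if not needs and self.descriptors:
            raise ValueError(f"{self.kind.value} specifier takes no descriptors")
        object.__setattr__(self, "descriptors", tuple(sorted(self.descriptors)))


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    """One harmonized gene/variant/disease/drug/association/evidence record."""

    source: Source
    gene: str
    variant: VariantSpecifier
    disease: str
    drugs: tuple[str, ...]
    association: Association
    tier: Tier
    references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "gene", self.gene.upper())
        if not self.drugs:
            raise ValueError("entry needs at least one drug")
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "references", tuple(self.references))

    @property
    def sort_key(self) -> tuple:
        return (
            self.gene,
            self.drugs,
            self.tier.value,
            self.association.value,
            self.variant.kind.value,
            self.variant.descriptors,
            self.disease,
            self.source.value,
            self.references,
        )


class SchemaError(ValueError):
    """A source file is missing a mandatory column."""


# ---------------------------------------------------------------------------
# Vocabulary maps (overridable via the YAML config; these are the defaults)
# ---------------------------------------------------------------------------

GDKD_TIER_MAP: Mapping[str, Tier] = {
    "nccn/fda": Tier.approved,
    "nccn": Tier.approved,
    "fda": Tier.approved,
    "late trials": Tier.late_trial,
    "early trials": Tier.early_trial,
    "case report": Tier.case_report,
    "preclinical": Tier.preclinical,
}

CIVIC_TIER_MAP: Mapping[str, Tier | None] = {
    "a": Tier.approved,       # "clinical routine"
    "b": Tier.late_trial,     # "clinical trials"
    "c": Tier.case_report,
    "d": Tier.preclinical,
    "e": None,                # inferential: below the preclinical floor, dropped
}

GDKD_ASSOCIATION_MAP: Mapping[str, Association] = {
    "response": Association.response,
    "sensitivity": Association.response,
    "increased benefit": Association.response,
    "resistance": Association.resistance,
    "no response": Association.resistance,
    "no sensitivity": Association.resistance,
    "reduced sensitivity": Association.resistance,
    "decreased sensitivity": Association.resistance,
    "reduced/decreased sensitivity": Association.resistance,
}

CIVIC_ASSOCIATION_MAP: Mapping[str, Association] = {
    "sensitivity": Association.response,
    "sensitivity/response": Association.response,
    "resistance": Association.resistance,
    "resistance or non-response": Association.resistance,
}

TARGET_KIND_MAP: Mapping[str, VariantKind] = {
    "amplification": VariantKind.amplification,
    "deletion": VariantKind.deletion,
    "biallelic inactivation": VariantKind.any_inactivating,
    "inactivating mutation": VariantKind.any_inactivating,
    "activating mutation": VariantKind.any_activating,
    "mutation": VariantKind.any_activating,
    "rearrangement": VariantKind.fusion,
    "fusion": VariantKind.fusion,
    "translocation": VariantKind.fusion,
}

GDKD_COLUMNS = {
    "gene": "Gene",
    "variant": "Variant",
    "disease": "Disease",
    "drugs": "Drug",
    "association": "Association",
    "tier": "Evidence level",
    "references": "References",
}

CIVIC_COLUMNS = {
    "gene": "gene",
    "variant": "variant",
    "disease": "disease",
    "drugs": "drugs",
    "evidence_type": "evidence_type",
    "tier": "evidence_level",
    "association": "clinical_significance",
    "references": "citation_id",
}

TARGET_COLUMNS = {
    "gene": "Gene",
    "alterations": "Types of alterations",
    "drugs": "Therapeutic agents",
}

EXPERT_COLUMNS = {
    "gene": "gene",
    "variant_kind": "variant_kind",
    "variant_descriptor": "variant_descriptor",
    "disease": "disease",
    "drugs": "drug",
    "association": "association",
    "tier": "tier",
    "references": "references",
}

# Free-text variant annotations in GDKD/CIViC that denote a variant class
# rather than a hotspot; checked in order.
_CLASS_PATTERNS: tuple[tuple[str, VariantKind], ...] = (
    (r"amplif", VariantKind.amplification),
    (r"copy number gain|\bgain\b(?!.of.function)", VariantKind.amplification),
    (r"copy number loss|\bdeletion\b|\bloss\b(?!.of.function)", VariantKind.deletion),
    (r"loss.of.function|inactivat|truncating", VariantKind.any_inactivating),
    (r"gain.of.function|activat", VariantKind.any_activating),
    (r"missense|\bany mutation\b|\bmutation\b$", VariantKind.any_missense),
    (r"wild.?type|wildtype", VariantKind.wild_type),
    (r"fusion|rearrangement|translocation", VariantKind.fusion),
)


def parse_variant_text(text: str, gene: str) -> VariantSpecifier:
    """Turn a free-text variant annotation into a typed specifier.

    Class annotations ("any missense mutation", "loss-of-function",
    "amplification", "BCR-ABL fusion", "wild type", ...) map to the
    corresponding kind; anything else is treated as one or more exact
    protein changes (comma/semicolon/slash separated).
    """
    raw = text.strip()
    low = raw.lower()
    for pattern, kind in _CLASS_PATTERNS:
        if re.search(pattern, low):
            if kind is VariantKind.fusion:
                partner = _fusion_partner(raw, gene)
                return VariantSpecifier(kind, (partner,))
            return VariantSpecifier(kind)
    parts = [p for p in re.split(r"[,;/]", raw) if p.strip()]
    descriptors = tuple(normalize_protein_change(p) for p in parts)
    return VariantSpecifier(VariantKind.exact_protein_change, descriptors)


def _fusion_partner(text: str, gene: str) -> str:
    """Extract the partner symbol from annotations like ``BCR-ABL1 fusion``."""
    gene = gene.upper()
    m = re.search(r"([A-Z0-9]+)\s*[-–]\s*([A-Z0-9]+)", text.upper())
    if m:
        a, b = m.group(1), m.group(2)
        if a == gene and b != gene:
            return b
        if b == gene and a != gene:
            return a
    return "any"


def _require_columns(df: pd.DataFrame, column_map: Mapping[str, str], needed: Iterable[str], what: str) -> None:
    for key in needed:
        col = column_map[key]
        if col not in df.columns:
            raise SchemaError(f"{what} file is missing mandatory column {col!r}")


def _split_multi(text: str) -> list[str]:
    return [p.strip() for p in re.split(r"[,;|]", text) if p.strip()]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_gdkd(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[KnowledgeBaseEntry]:
    """Load a GDKD-style export.

    GDKD is a manually curated database of predictive biomarkers annotating
    cancer type, gene, variant, response/resistance and an evidence label
    (NCCN/FDA, late/early trials, case report, preclinical).  Rows with an
    unmappable evidence or association label are skipped with a warning.
    """
    cols = {**GDKD_COLUMNS, **(column_map or {})}
    df = _read_table(path)
    _require_columns(df, cols, ["gene", "variant", "disease", "drugs", "association", "tier"], "GDKD")
    entries: list[KnowledgeBaseEntry] = []
    for idx, row in df.iterrows():
        tier = GDKD_TIER_MAP.get(str(row[cols["tier"]]).strip().lower())
        if tier is None:
            logger.warning("GDKD row %d skipped: unmappable evidence label %r", idx, row[cols["tier"]])
            continue
        association = GDKD_ASSOCIATION_MAP.get(str(row[cols["association"]]).strip().lower())
        if association is None:
            logger.warning("GDKD row %d skipped: unmappable association %r", idx, row[cols["association"]])
            continue
        gene = str(row[cols["gene"]]).strip().upper()
        if not gene:
            logger.warning("GDKD row %d skipped: empty gene symbol", idx)
            continue
        refs = _split_multi(str(row.get(cols.get("references", ""), ""))) if cols.get("references") in df.columns else []
        entries.append(
            KnowledgeBaseEntry(
                source=Source.GDKD,
                gene=gene,
                variant=parse_variant_text(str(row[cols["variant"]]), gene),
                disease=str(row[cols["disease"]]).strip(),
                drugs=tuple(_split_multi(str(row[cols["drugs"]]))),
                association=association,
                tier=tier,
                references=tuple(refs),
            )
        )
    return entries


def load_civic(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[KnowledgeBaseEntry]:
    """Load a CIViC-style evidence export.

    Only predictive evidence is used (CIViC also carries prognostic and
    diagnostic items).  Evidence levels map A (clinical routine) -> approved,
    B (clinical trials) -> late_trial, C -> case_report, D -> preclinical;
    level E (inferential) falls below the preclinical floor of the six-level
    system and is dropped.
    """
    cols = {**CIVIC_COLUMNS, **(column_map or {})}
    df = _read_table(path)
    _require_columns(df, cols, ["gene", "variant", "disease", "drugs", "evidence_type", "tier", "association"], "CIViC")
    entries: list[KnowledgeBaseEntry] = []
    for idx, row in df.iterrows():
        if str(row[cols["evidence_type"]]).strip().lower() != "predictive":
            continue
        level = str(row[cols["tier"]]).strip().lower()
        tier = CIVIC_TIER_MAP.get(level, None) if level in CIVIC_TIER_MAP else False
        if tier is False:
            logger.warning("CIViC row %d skipped: unmappable evidence level %r", idx, row[cols["tier"]])
            continue
        if tier is None:
            logger.info("CIViC row %d dropped: level E (inferential)", idx)
            continue
        association = CIVIC_ASSOCIATION_MAP.get(str(row[cols["association"]]).strip().lower())
        if association is None:
            logger.warning("CIViC row %d skipped: unmappable clinical significance %r", idx, row[cols["association"]])
            continue
        gene = str(row[cols["gene"]]).strip().upper()
        if not gene:
            logger.warning("CIViC row %d skipped: empty gene symbol", idx)
            continue
        refs = _split_multi(str(row.get(cols.get("references", ""), ""))) if cols.get("references") in df.columns else []
        entries.append(
            KnowledgeBaseEntry(
                source=Source.CIVIC,
                gene=gene,
                variant=parse_variant_text(str(row[cols["variant"]]), gene),
                disease=str(row[cols["disease"]]).strip(),
                drugs=tuple(_split_multi(str(row[cols["drugs"]]))),
                association=association,
                tier=tier,
                references=tuple(refs),
            )
        )
    return entries


def load_target(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    kind_map: Mapping[str, VariantKind] | None = None,
) -> list[KnowledgeBaseEntry]:
    """Load a TARGET-style table.

    TARGET annotates genes, their recurrent alteration types and example
    therapeutic agents, but is not variant-specific, provides no references
    and no evidence levels — entries get ``tier=unranked`` and are reported
    in a separate gene-level section downstream.  Alteration free text is
    resolved through a keyword map; unrecognized text skips the row (the
    kind is never guessed).
    """
    cols = {**TARGET_COLUMNS, **(column_map or {})}
    kinds = {k.lower(): v for k, v in (kind_map or TARGET_KIND_MAP).items()}
    df = _read_table(path)
    _require_columns(df, cols, ["gene", "alterations", "drugs"], "TARGET")
    entries: list[KnowledgeBaseEntry] = []
    for idx, row in df.iterrows():
        gene = str(row[cols["gene"]]).strip().upper()
        if not gene:
            logger.warning("TARGET row %d skipped: empty gene symbol", idx)
            continue
        drugs = tuple(_split_multi(str(row[cols["drugs"]])))
        if not drugs:
            logger.warning("TARGET row %d skipped: no therapeutic agents", idx)
            continue
        for token in _split_multi(str(row[cols["alterations"]])):
            kind = kinds.get(token.strip().lower())
            if kind is None:
                logger.warning("TARGET row %d: unrecognized alteration %r skipped", idx, token)
                continue
            spec = (
                VariantSpecifier(kind, ("any",))
                if kind is VariantKind.fusion
                else VariantSpecifier(kind)
            )
            entries.append(
                KnowledgeBaseEntry(
                    source=Source.TARGET,
                    gene=gene,
                    variant=spec,
                    disease="",
                    drugs=drugs,
                    association=Association.response,
                    tier=Tier.unranked,
                )
            )
    return entries


_TIER_BY_NAME = {t.value: t for t in Tier}
_KIND_BY_NAME = {k.value: k for k in VariantKind}
_ASSOC_BY_NAME = {a.value: a for a in Association}
_SOURCE_BY_NAME = {s.value: s for s in Source}


def load_expert(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[KnowledgeBaseEntry]:
    """Load expert rules already written in the harmonized schema."""
    cols = {**EXPERT_COLUMNS, **(column_map or {})}
    df = _read_table(path)
    _require_columns(df, cols, ["gene", "variant_kind", "disease", "drugs", "association", "tier"], "expert rules")
    entries: list[KnowledgeBaseEntry] = []
    for idx, row in df.iterrows():
        kind = _KIND_BY_NAME.get(str(row[cols["variant_kind"]]).strip())
        tier = _TIER_BY_NAME.get(str(row[cols["tier"]]).strip())
        association = _ASSOC_BY_NAME.get(str(row[cols["association"]]).strip())
        if kind is None or tier is None or association is None:
            logger.warning("expert-rules row %d skipped: unrecognized vocabulary", idx)
            continue
        descriptor = str(row.get(cols.get("variant_descriptor", ""), "")).strip()
        if kind is VariantKind.exact_protein_change:
            descriptors = tuple(normalize_protein_change(d) for d in _split_multi(descriptor))
        elif kind is VariantKind.fusion:
            descriptors = (descriptor or "any",)
        else:
            descriptors = ()
        refs = _split_multi(str(row.get(cols.get("references", ""), ""))) if cols.get("references") in df.columns else []
        entries.append(
            KnowledgeBaseEntry(
                source=Source.EXPERT,
                gene=str(row[cols["gene"]]).strip().upper(),
                variant=VariantSpecifier(kind, descriptors),
                disease=str(row[cols["disease"]]).strip(),
                drugs=tuple(_split_multi(str(row[cols["drugs"]]))),
                association=association,
                tier=tier,
                references=tuple(refs),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Aggregation & disease harmonization
# ---------------------------------------------------------------------------

def aggregate_entries(entries: Sequence[KnowledgeBaseEntry]) -> list[KnowledgeBaseEntry]:
    """Merge entries that differ only in their variant descriptors.

    Entries in the same gene sharing source, disease, drugs, evidence tier,
    association and variant kind are collapsed into a single entry whose
    descriptor set (and reference list) is the union.  The operation is
    idempotent and the output order is deterministic.
    """
    groups: dict[tuple, list[KnowledgeBaseEntry]] = {}
    for e in entries:
        key = (e.source, e.gene, e.disease, e.drugs, e.association, e.tier, e.variant.kind)
        groups.setdefault(key, []).append(e)
    merged: list[KnowledgeBaseEntry] = []
    for group in groups.values():
        first = group[0]
        descriptors = sorted({d for e in group for d in e.variant.descriptors})
        references = sorted({r for e in group for r in e.references})
        merged.append(
            replace(
                first,
                variant=VariantSpecifier(first.variant.kind, tuple(descriptors)),
                references=tuple(references),
            )
        )
    return sorted(merged, key=lambda e: e.sort_key)


def harmonize_disease(raw_label: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Map a cancer-type label onto its canonical form.

    Lookup is case-insensitive; labels absent from the synonym table pass
    through verbatim (stripped) and are flagged via the log so the user can
    extend the table.
    """
    label = raw_label.strip()
    if synonym_map:
        lowered = {k.strip().lower(): v for k, v in synonym_map.items()}
        hit = lowered.get(label.lower())
        if hit is not None:
            return hit
        canonical = {v.strip().lower() for v in synonym_map.values()}
        if label.lower() not in canonical:
            logger.info("cancer-type label %r not in synonym table; passed through", label)
    return label


# ---------------------------------------------------------------------------
# Harmonized CSV round-trip
# ---------------------------------------------------------------------------

KB_CSV_COLUMNS = [
    "source",
    "gene",
    "variant_kind",
    "variant_descriptor",
    "disease",
    "drug",
    "association",
    "tier",
    "references",
]


def write_kb(entries: Sequence[KnowledgeBaseEntry], path: str | Path) -> None:
    """Serialize a harmonized knowledge base to CSV (one entry per row).

    Multi-valued fields (descriptors, drugs, references) are pipe-separated.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(KB_CSV_COLUMNS)
        for e in sorted(entries, key=lambda e: e.sort_key):
            writer.writerow(
                [
                    e.source.value,
                    e.gene,
                    e.variant.kind.value,
                    "|".join(e.variant.descriptors),
                    e.disease,
                    "|".join(e.drugs),
                    e.association.value,
                    e.tier.value,
                    "|".join(e.references),
                ]
            )


def read_kb(path: str | Path) -> list[KnowledgeBaseEntry]:
    """Read back a harmonized knowledge-base CSV written by :func:`write_kb`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in KB_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"harmonized KB file is missing columns {missing}")
    entries = []
    for _, row in df.iterrows():
        descriptors = tuple(d for d in row["variant_descriptor"].split("|") if d)
        entries.append(
            KnowledgeBaseEntry(
                source=_SOURCE_BY_NAME[row["source"]],
                gene=row["gene"],
                variant=VariantSpecifier(_KIND_BY_NAME[row["variant_kind"]], descriptors),
                disease=row["disease"],
                drugs=tuple(d for d in row["drug"].split("|") if d),
                association=_ASSOC_BY_NAME[row["association"]],
                tier=_TIER_BY_NAME[row["tier"]],
                references=tuple(r for r in row["references"].split("|") if r),
            )
        )
    return entries
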