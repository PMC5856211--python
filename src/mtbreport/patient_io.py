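"""Per-patient somatic variant input.

Readers for the three variant tables a molecular tumor board pipeline hands
over: an SNV/indel table (MAF-compatible column names honored), a GISTIC 2.0
``all_thresholded.by_genes`` copy-number matrix, and a gene-fusion list.
Quality filtering is assumed to have happened upstream; matching is purely
gene-symbol + protein-change based, so genomic coordinates are never
interpreted.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from mtbreport.knowledgebase import normalize_protein_change

logger = logging.getLogger(__name__)


class SNVClass(str, Enum):
    missense = "missense"
    stopgain = "stopgain"
    stoploss = "stoploss"
    frameshift_indel = "frameshift_indel"
    inframe_indel = "inframe_indel"
    splice = "splice"
    silent = "silent"
    other = "other"


class CNVStatus(str, Enum):
    deep_loss = "deep_loss"
    high_amplification = "high_amplification"
    not_actionable = "not_actionable"


@dataclass(frozen=True)
class SNV:
    """A coding single-nucleotide variant or small indel.

    Silent variants are retained (for QC totals) but flagged non-actionable
    and never reach matching.
    """

    gene: str
    classification: SNVClass
    protein_change: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.upper())
        object.__setattr__(self, "protein_change", normalize_protein_change(self.protein_change))

    @property
    def is_silent(self) -> bool:
        return self.classification is SNVClass.silent


@dataclass(frozen=True)
class CNV:
    """A gene-level discretized copy-number call.

    ``gistic_value`` follows GISTIC's thresholded convention {-2..2}; only
    high-level events (|value| = 2, approximating homozygous events) are
    actionable.
    """

    gene: str
    gistic_value: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.upper())
        if self.gistic_value not in (-2, -1, 0, 1, 2):
            raise ValueError(f"GISTIC thresholded value must be in -2..2, got {self.gistic_value}")

    @property
    def status(self) -> CNVStatus:
        if self.gistic_value == -2:
            return CNVStatus.deep_loss
        if self.gistic_value == 2:
            return CNVStatus.high_amplification
        return CNVStatus.not_actionable


@dataclass(frozen=True)
class Fusion:
    gene5p: str
    gene3p: str

    def __post_init__(self) -> None:
        if not self.gene5p or not self.gene3p:
            raise ValueError("fusion partners must be non-empty")
        object.__setattr__(self, "gene5p", self.gene5p.upper())
        object.__setattr__(self, "gene3p", self.gene3p.upper())


@dataclass
class PatientProfile:
    """Cancer-type label plus the somatic variants of one case."""

    case_id: str
    cancer_type: str
    snvs: list[SNV] = field(default_factory=list)
    cnvs: list[CNV] = field(default_factory=list)
    fusions: list[Fusion] = field(default_factory=list)

    def altered_genes(self) -> set[str]:
        """Genes with any non-silent SNV, actionable CNV or fusion."""
        genes = {s.gene for s in self.snvs if not s.is_silent}
        genes |= {c.gene for c in self.cnvs if c.status is not CNVStatus.not_actionable}
        genes |= {g for f in self.fusions for g in (f.gene5p, f.gene3p)}
        return genes


SNV_COLUMNS = {
    "gene": ["Hugo_Symbol", "gene", "Gene"],
    "classification": ["Variant_Classification", "classification", "variant_classification"],
    "protein_change": ["HGVSp_Short", "protein_change", "Protein_Change", "amino_acid_change"],
}

# MAF Variant_Classification vocabulary -> internal classes
SNV_CLASS_MAP: Mapping[str, SNVClass] = {
    "missense_mutation": SNVClass.missense,
    "missense": SNVClass.missense,
    "nonsense_mutation": SNVClass.stopgain,
    "stopgain": SNVClass.stopgain,
    "nonstop_mutation": SNVClass.stoploss,
    "stoploss": SNVClass.stoploss,
    "frame_shift_del": SNVClass.frameshift_indel,
    "frame_shift_ins": SNVClass.frameshift_indel,
    "frameshift_indel": SNVClass.frameshift_indel,
    "frameshift": SNVClass.frameshift_indel,
    "in_frame_del": SNVClass.inframe_indel,
    "in_frame_ins": SNVClass.inframe_indel,
    "inframe_indel": SNVClass.inframe_indel,
    "splice_site": SNVClass.splice,
    "splice": SNVClass.splice,
    "silent": SNVClass.silent,
    "synonymous": SNVClass.silent,
}


def _resolve_column(df: pd.DataFrame, candidates: Sequence[str]) -> str | None:
    for c in candidates:
        if c in df.columns:
            return c
    return None


def read_snv_table(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[SNV]:
    """Read a tab-delimited SNV/indel table (MAF-compatible subset).

    Needs gene, variant-classification and protein-change columns; MAF names
    (``Hugo_Symbol``/``Variant_Classification``/``HGVSp_Short``) are
    recognized by default and can be overridden per key via ``column_map``.
    Unknown classification labels map to ``other`` with a log message.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    resolved: dict[str, str | None] = {}
    for key, candidates in SNV_COLUMNS.items():
        override = (column_map or {}).get(key)
        resolved[key] = override if override else _resolve_column(df, candidates)
    if resolved["gene"] is None or resolved["gene"] not in df.columns:
        raise ValueError("SNV table is missing a gene symbol column (e.g. Hugo_Symbol)")
    snvs: list[SNV] = []
    for idx, row in df.iterrows():
        gene = str(row[resolved["gene"]]).strip()
        if not gene:
            continue
        raw_class = str(row[resolved["classification"]]).strip() if resolved["classification"] else ""
        cls = SNV_CLASS_MAP.get(raw_class.lower())
        if cls is None:
            logger.info("SNV row %d: unknown classification %r mapped to 'other'", idx, raw_class)
            cls = SNVClass.other
        change = str(row[resolved["protein_change"]]).strip() if resolved["protein_change"] else ""
        snvs.append(SNV(gene=gene, classification=cls, protein_change=change))
    return snvs


def write_snv_table(snvs: Sequence[SNV], path: str | Path) -> None:
    """Write SNVs to the internal tab-delimited layout (round-trips with
    :func:`read_snv_table`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene", "classification", "protein_change"])
        for s in snvs:
            writer.writerow([s.gene, s.classification.value, s.protein_change])


# Annotation columns GISTIC places before the per-sample columns.
_GISTIC_META_COLUMNS = {"locus id", "cytoband", "gene id"}


def read_gistic_thresholded(path: str | Path, sample_id: str) -> list[CNV]:
    """Extract one sample's gene-level CNVs from a GISTIC 2.0
    ``all_thresholded.by_genes`` matrix.

    First column holds gene symbols; ``Locus ID``/``Cytoband`` annotation
    columns are ignored; every other column is a sample of integer calls in
    {-2..2}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gene_col = df.columns[0]
    sample_cols = [
        c for c in df.columns[1:] if c.strip().lower() not in _GISTIC_META_COLUMNS
    ]
    if sample_id not in sample_cols:
        raise KeyError(
            f"sample {sample_id!r} not in matrix; available samples: {sorted(sample_cols)}"
        )
    cnvs: list[CNV] = []
    for idx, row in df.iterrows():
        cell = str(row[sample_id]).strip()
        try:
            value = int(cell)
        except ValueError as exc:
            raise ValueError(
                f"non-integer GISTIC cell {cell!r} at row {idx}, column {sample_id!r}"
            ) from exc
        cnvs.append(CNV(gene=str(row[gene_col]).strip(), gistic_value=value))
    return cnvs


def read_fusions(path: str | Path) -> list[Fusion]:
    """Read gene fusions from a two-column table or ``GENE1-GENE2`` strings.

    Partner order (5' then 3') is preserved; malformed rows are skipped with
    a log message.
    """
    fusions: list[Fusion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                parts = [p.strip() for p in line.split("\t") if p.strip()]
            else:
                parts = [p.strip() for p in line.split("-") if p.strip()]
            if len(parts) != 2:
                logger.warning("fusion line %d malformed (%r); skipped", lineno, line)
                continue
            if lineno == 1 and {p.lower() for p in parts} & {"gene5p", "gene3p", "gene1", "gene2"}:
                continue  # header row
            fusions.append(Fusion(gene5p=parts[0], gene3p=parts[1]))
    return fusions
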