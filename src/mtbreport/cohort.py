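"""Cohort-scale actionability statistics.

Builds the molecular status matrix of actionable genes (four mutually
exclusive categories: wild type, mutated, high-level amplification, deep
loss) and the per-level / cumulative patient-coverage statistics.  Coverage
counts evidence for response only and ignores wild-type matches and
resistance evidence, except at level A1 where such findings are clinically
decisive (e.g. KRAS/NRAS wild type in colorectal cancer) and are therefore
counted.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from mtbreport.evidence import COARSE_LEVELS, cumulative_level_sets
from mtbreport.patient_io import CNVStatus, PatientProfile
from mtbreport.report import MTBReport, ReportRow

logger = logging.getLogger(__name__)

STATUS_CATEGORIES = ("wild_type", "mutated", "high_amplification", "deep_loss")


def molecular_status_matrix(
    profiles: Sequence[PatientProfile], gene_list: Sequence[str]
) -> pd.DataFrame:
    """Gene × sample matrix of molecular status over an actionable-gene list.

    Cells take one of four categories; a gene with both a non-silent SNV and
    a high-level CNV in the same sample is recorded as mutated (the more
    specific annotation; the conflict is logged).  Genes without any
    alteration in any sample are removed.
    """
    genes = [g.upper() for g in gene_list]
    samples = [p.case_id for p in profiles]
    matrix = pd.DataFrame("wild_type", index=genes, columns=samples, dtype=object)
    for p in profiles:
        mutated = {s.gene for s in p.snvs if not s.is_silent}
        amplified = {c.gene for c in p.cnvs if c.status is CNVStatus.high_amplification}
        lost = {c.gene for c in p.cnvs if c.status is CNVStatus.deep_loss}
        for g in genes:
            if g in mutated:
                if g in amplified or g in lost:
                    logger.info(
                        "sample %s gene %s has both mutation and high-level CNV; recorded as mutated",
                        p.case_id, g,
                    )
                matrix.loc[g, p.case_id] = "mutated"
            elif g in lost:
                matrix.loc[g, p.case_id] = "deep_loss"
            elif g in amplified:
                matrix.loc[g, p.case_id] = "high_amplification"
    keep = [g for g in genes if not (matrix.loc[g] == "wild_type").all()]
    return matrix.loc[keep]


def _qualifies(row: ReportRow) -> bool:
    """Coverage qualification: response rows from non-wild-type matches, or
    any A1 row (the A1 exception keeps wild-type and resistance findings)."""
    if row.level_coarse == "A1":
        return True
    return row.association == "response" and row.match_mode != "wild_type"


def coverage_by_level(reports: Sequence[MTBReport]) -> dict[str, float]:
    """Fraction of patients with at least one qualifying association at each
    of the six evidence levels (independently)."""
    n = len(reports)
    out = {lvl: 0.0 for lvl in COARSE_LEVELS}
    if n == 0:
        return out
    for lvl in COARSE_LEVELS:
        hit = sum(
            1
            for rep in reports
            if any(r.level_coarse == lvl and _qualifies(r) for r in rep.rows)
        )
        out[lvl] = hit / n
    return out


def cumulative_coverage(reports: Sequence[MTBReport]) -> list[float]:
    """Cumulative fraction of patients with at least one qualifying
    association at increasing levels of evidence (A1, then A1+B1, ...)."""
    n = len(reports)
    prefixes = cumulative_level_sets()
    if n == 0:
        return [0.0] * len(prefixes)
    fractions = []
    for prefix in prefixes:
        hit = sum(
            1
            for rep in reports
            if any(r.level_coarse in prefix and _qualifies(r) for r in rep.rows)
        )
        fractions.append(hit / n)
    return fractions


def genes_per_level(reports: Sequence[MTBReport]) -> dict[str, tuple[float, float]]:
    """Mean ± SD of distinct actionable genes per patient at each level.

    Averaged over the patients with at least one qualifying association at
    that level (population SD); levels without any such patient yield
    (0.0, 0.0).  The same wild-type/resistance exclusion as the coverage
    panels applies.
    """
    out: dict[str, tuple[float, float]] = {}
    for lvl in COARSE_LEVELS:
        counts = []
        for rep in reports:
            genes = {r.gene for r in rep.rows if r.level_coarse == lvl and _qualifies(r)}
            if genes:
                counts.append(len(genes))
        if counts:
            arr = np.asarray(counts, dtype=float)
            out[lvl] = (float(arr.mean()), float(arr.std(ddof=0)))
        else:
            out[lvl] = (0.0, 0.0)
    return out
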