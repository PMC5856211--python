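"""Per-patient MTB report construction and rendering.

A report compiles all actionable variants of one patient: QC summaries,
per-level counts of gene–drug predictive associations, and a ranked table
with one row per (match, drug) pair.  Rows are ranked by (1) drug frequency
— the number of times the drug appears associated with response, so the
best-supported therapeutic options come first and all rows of one drug stay
contiguous, (2) evidence level (A1 > B1 > A2 > B2 > A3 > B3) and (3) gene.
Association semantics are colored in rendered output: response green,
resistance red, variants of unknown significance gray.
"""

from __future__ import annotations

import csv
import html as _html
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from mtbreport.evidence import COARSE_LEVELS, EvidenceLevel, assign_level
from mtbreport.knowledgebase import Tier
from mtbreport.matching import MatchMode, MatchRecord
from mtbreport.patient_io import CNVStatus, PatientProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReportRow:
    """One gene-variant/drug predictive association in the ranked table."""

    gene: str
    patient_variant: str
    matched_variant: str
    disease: str
    drug: str
    association: str  # "response" | "resistance"
    level: EvidenceLevel
    known_significance: bool
    match_mode: str
    source: str
    references: tuple[str, ...] = ()

    @property
    def level_display(self) -> str:
        return self.level.display

    @property
    def level_coarse(self) -> str:
        return self.level.coarse


@dataclass(frozen=True)
class TargetSectionHit:
    """Gene-level hit from a variant-unspecific, unranked source (TARGET)."""

    gene: str
    patient_variant: str
    alteration_kind: str
    drugs: tuple[str, ...]
    source: str


@dataclass
class MTBReport:
    case_id: str
    cancer_type: str
    qc: dict = field(default_factory=dict)
    rows: list[ReportRow] = field(default_factory=list)
    level_counts: dict = field(default_factory=dict)
    target_section: list[TargetSectionHit] = field(default_factory=list)


def _response_counts(rows: Sequence[ReportRow]) -> Counter:
    return Counter(r.drug for r in rows if r.association == "response")


def rank_rows(rows: Sequence[ReportRow]) -> list[ReportRow]:
    """Stable ranked order of report rows.

    Drugs are ordered by descending response-row count, ties broken by the
    drug's best evidence level and then drug name; within one drug's block,
    response rows precede resistance rows, each sub-block sorted by level
    then gene.
    """
    if not rows:
        return []
    n_response = _response_counts(rows)
    best_level: dict[str, int] = {}
    for r in rows:
        best_level[r.drug] = min(best_level.get(r.drug, 99), r.level.rank)

    def key(r: ReportRow):
        return (
            -n_response.get(r.drug, 0),
            best_level[r.drug],
            r.drug,
            0 if r.association == "response" else 1,
            r.level.rank,
            r.gene,
            r.patient_variant,
            r.matched_variant,
            r.source,
        )

    return sorted(rows, key=key)


def drug_support(report: MTBReport) -> dict[str, float]:
    """Per-drug support: response rows for the drug as a percentage of all
    ranked rows, to one decimal."""
    total = len(report.rows)
    if total == 0:
        return {}
    n_response = _response_counts(report.rows)
    return {
        drug: round(100.0 * n_response.get(drug, 0) / total, 1)
        for drug in sorted({r.drug for r in report.rows})
    }


def build_report(profile: PatientProfile, matches: Sequence[MatchRecord]) -> MTBReport:
    """Assemble the per-patient report from the profile and its matches.

    Ranked matches are expanded one row per drug and leveled against the
    patient's cancer type; unranked (TARGET) matches are routed to the
    gene-level section.  Level counts use the six coarse levels.
    """
    rows: list[ReportRow] = []
    target_hits: list[TargetSectionHit] = []
    for m in matches:
        if m.entry.tier is Tier.unranked:
            target_hits.append(
                TargetSectionHit(
                    gene=m.gene,
                    patient_variant=m.variant_display,
                    alteration_kind=m.entry.variant.kind.value,
                    drugs=m.entry.drugs,
                    source=m.entry.source.value,
                )
            )
            continue
        level = assign_level(m, profile.cancer_type)
        if level is None:  # defensive; unranked handled above
            continue
        matched = "|".join(m.entry.variant.descriptors) or m.entry.variant.kind.value
        for drug in m.entry.drugs:
            rows.append(
                ReportRow(
                    gene=m.gene,
                    patient_variant=m.variant_display,
                    matched_variant=matched,
                    disease=m.entry.disease,
                    drug=drug,
                    association=m.entry.association.value,
                    level=level,
                    known_significance=m.known_significance,
                    match_mode=m.match_mode.value,
                    source=m.entry.source.value,
                    references=m.entry.references,
                )
            )
    ranked = rank_rows(rows)
    level_counts = {lvl: 0 for lvl in COARSE_LEVELS}
    for r in ranked:
        level_counts[r.level_coarse] += 1
    level_counts = {k: v for k, v in level_counts.items() if v}
    qc = {
        "n_snvs": len(profile.snvs),
        "n_snvs_silent": sum(1 for s in profile.snvs if s.is_silent),
        "n_cnvs": len(profile.cnvs),
        "n_cnvs_actionable": sum(
            1 for c in profile.cnvs if c.status is not CNVStatus.not_actionable
        ),
        "n_fusions": len(profile.fusions),
    }
    return MTBReport(
        case_id=profile.case_id,
        cancer_type=profile.cancer_type,
        qc=qc,
        rows=ranked,
        level_counts=level_counts,
        target_section=sorted(target_hits, key=lambda h: (h.gene, h.alteration_kind, h.drugs)),
    )


CSV_COLUMNS = [
    "gene",
    "patient_variant",
    "matched_variant",
    "disease",
    "drug",
    "association",
    "level",
    "level_detail",
    "known_significance",
    "match_mode",
    "source",
    "references",
]

_FORMATS = ("markdown", "html", "csv")


def render_report(
    report: MTBReport,
    format: str = "markdown",
    out_dir: str | Path | None = None,
    drug_classes: Mapping[str, str] | None = None,
) -> str | Path:
    """Render a report deterministically.

    Returns the rendered text, or — when ``out_dir`` is given — writes
    ``<case_id>.<ext>`` there and returns the path.  ``drug_classes``
    optionally maps specific drugs to display classes (e.g. everolimus ->
    "mTOR inhibitor"); it affects display grouping only.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {', '.join(_FORMATS)}")
    if format == "csv":
        text = _render_csv(report)
        ext = "csv"
    elif format == "markdown":
        text = _render_markdown(report, drug_classes or {})
        ext = "md"
    else:
        text = _render_html(report, drug_classes or {})
        ext = "html"
    if out_dir is None:
        return text
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{report.case_id}.{ext}"
    path.write_text(text)
    return path


def _row_values(r: ReportRow) -> list[str]:
    return [
        r.gene,
        r.patient_variant,
        r.matched_variant,
        r.disease,
        r.drug,
        r.association,
        r.level_coarse,
        r.level_display,
        "yes" if r.known_significance else "no",
        r.match_mode,
        r.source,
        "|".join(r.references),
    ]


def _render_csv(report: MTBReport) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for r in report.rows:
        writer.writerow(_row_values(r))
    return buf.getvalue()


def _display_drug(drug: str, drug_classes: Mapping[str, str]) -> str:
    cls = drug_classes.get(drug.lower())
    return f"{drug} [{cls}]" if cls else drug


def _render_markdown(report: MTBReport, drug_classes: Mapping[str, str]) -> str:
    lines: list[str] = []
    lines.append(f"# MTB report — {report.case_id}")
    lines.append("")
    lines.append("## Patient information")
    lines.append("")
    lines.append(f"- Cancer type: {report.cancer_type}")
    qc = report.qc
    lines.append(
        f"- SNVs/indels: {qc.get('n_snvs', 0)} ({qc.get('n_snvs_silent', 0)} silent)"
    )
    lines.append(
        f"- CNVs: {qc.get('n_cnvs', 0)} ({qc.get('n_cnvs_actionable', 0)} high-level)"
    )
    lines.append(f"- Fusions: {qc.get('n_fusions', 0)}")
    lines.append("")
    lines.append("## Gene–drug predictive associations")
    lines.append("")
    lines.append(
        "Associations are ranked by drug support, evidence level "
        "(A1 > B1 > A2 > B2 > A3 > B3) and gene. Association semantics: "
        "response = green, resistance = red; variants of unknown "
        "significance (repurposed) = gray."
    )
    lines.append("")
    if report.level_counts:
        counts = ", ".join(f"{k}: {v}" for k, v in sorted(report.level_counts.items(), key=lambda kv: COARSE_LEVELS.index(kv[0])))
        lines.append(f"Associations per level — {counts}")
    else:
        lines.append("No ranked gene–drug associations found.")
    lines.append("")
    if report.rows:
        header = [
            "Gene", "Patient variant", "Known variant", "Cancer type",
            "Drug", "Association", "Level", "Significance",
        ]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for r in report.rows:
            sig = "known" if r.known_significance else "repurposed"
            lines.append(
                "| "
                + " | ".join(
                    [
                        r.gene,
                        r.patient_variant,
                        r.matched_variant,
                        r.disease,
                        _display_drug(r.drug, drug_classes),
                        r.association,
                        r.level_display,
                        sig,
                    ]
                )
                + " |"
            )
        lines.append("")
    if report.target_section:
        lines.append("## Gene-level hits (TARGET, no evidence level)")
        lines.append("")
        for h in report.target_section:
            lines.append(
                f"- {h.gene} ({h.alteration_kind}; {h.patient_variant}): "
                + ", ".join(h.drugs)
            )
        lines.append("")
    return "\n".join(lines) + "\n"


_COLOR = {"response": "#1a7f37", "resistance": "#b91c1c"}


def _render_html(report: MTBReport, drug_classes: Mapping[str, str]) -> str:
    md_rows = []
    for r in report.rows:
        color = "#6b7280" if not r.known_significance else _COLOR[r.association]
        cells = [
            r.gene, r.patient_variant, r.matched_variant, r.disease,
            _display_drug(r.drug, drug_classes), r.association, r.level_display,
            "known" if r.known_significance else "repurposed",
        ]
        md_rows.append(
            f'<tr style="color:{color}">'
            + "".join(f"<td>{_html.escape(c)}</td>" for c in cells)
            + "</tr>"
        )
    counts = ", ".join(
        f"{k}: {v}"
        for k, v in sorted(report.level_counts.items(), key=lambda kv: COARSE_LEVELS.index(kv[0]))
    )
    target = "".join(
        f"<li>{_html.escape(h.gene)} ({_html.escape(h.alteration_kind)}): "
        f"{_html.escape(', '.join(h.drugs))}</li>"
        for h in report.target_section
    )
    qc = report.qc
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>MTB report {_html.escape(report.case_id)}</title></head><body>"
        f"<h1>MTB report — {_html.escape(report.case_id)}</h1>"
        "<h2>Patient information</h2><ul>"
        f"<li>Cancer type: {_html.escape(report.cancer_type)}</li>"
        f"<li>SNVs/indels: {qc.get('n_snvs', 0)} ({qc.get('n_snvs_silent', 0)} silent)</li>"
        f"<li>CNVs: {qc.get('n_cnvs', 0)} ({qc.get('n_cnvs_actionable', 0)} high-level)</li>"
        f"<li>Fusions: {qc.get('n_fusions', 0)}</li></ul>"
        "<h2>Gene–drug predictive associations</h2>"
        "<p>Response = green, resistance = red, unknown significance = gray.</p>"
        f"<p>Associations per level — {_html.escape(counts) if counts else 'none'}</p>"
        "<table border='1'><tr><th>Gene</th><th>Patient variant</th>"
        "<th>Known variant</th><th>Cancer type</th><th>Drug</th>"
        "<th>Association</th><th>Level</th><th>Significance</th></tr>"
        + "".join(md_rows)
        + "</table>"
        + (f"<h2>Gene-level hits (TARGET)</h2><ul>{target}</ul>" if target else "")
        + "</body></html>"
    )
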