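"""Synthetic knowledge bases and patient cohorts with planted ground truth.

The generator emulates both sides of the pipeline so every stage is testable
without external downloads: a miniature harmonized knowledge base covering
every variant-specifier kind, both association directions, every evidence
tier and two diseases; and cohorts of patient profiles with planted
actionable variants whose expected match mode and evidence level are known
by construction.

Planting is deterministic (assignment, not sampling), so per-level and
cumulative coverage targets are met exactly rather than binomially.  Every
planted variant's gene carries exactly one knowledge-base entry, and
distractor variants (silent SNVs, low-level CNVs, mutations in off-kb genes)
are guaranteed to produce no matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from mtbreport.knowledgebase import (
    Association,
    KnowledgeBaseEntry,
    Source,
    Tier,
    VariantKind,
    VariantSpecifier,
)
from mtbreport.patient_io import CNV, Fusion, PatientProfile, SNV, SNVClass

DISEASE_SAME = "alpha carcinoma"
DISEASE_OTHER = "beta carcinoma"

# Plantable match scenarios: kb variant kind + the patient alteration used to
# hit it, with the expected match mode.
PLANT_KINDS = (
    "exact_hotspot",      # missense with listed protein change -> exact_change
    "any_missense",       # unlisted missense vs any-missense entry
    "stopgain_lof",       # stopgain repurposed onto loss-of-function entry
    "amplification",      # GISTIC +2 vs amplification entry
    "deep_loss",          # GISTIC -2 vs deletion entry
    "fusion",             # fusion with matching partner
)

_RANKED_TIERS = (
    Tier.approved,
    Tier.late_trial,
    Tier.early_trial,
    Tier.case_report,
    Tier.preclinical,
)

_STRENGTH_TIERS = {
    "1": (Tier.approved,),
    "2": (Tier.late_trial, Tier.early_trial, Tier.case_report),
    "3": (Tier.preclinical,),
}

# Default cohort design: per-level planting increments whose cumulative sums
# are the coverage profile the method reports on an exome-wide pan-cancer
# cohort (A1 9.9%, B1 22.7%, A2 64.1%, B2 89%, A3 90.6%, B3 94%).
DEFAULT_COHORT_DESIGN: dict[str, float] = {
    "A1": 0.099,
    "B1": 0.128,
    "A2": 0.414,
    "B2": 0.249,
    "A3": 0.016,
    "B3": 0.034,
}


@dataclass(frozen=True)
class PlantedMatch:
    case_id: str
    gene: str
    expected_mode: str
    expected_level: str  # coarse display, e.g. "B2"
    drug: str


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort."""

    matches: list[PlantedMatch] = field(default_factory=list)
    design: dict[str, float] = field(default_factory=dict)
    n_patients: int = 0

    def expected_coverage(self) -> dict[str, float]:
        """Exact per-level coverage implied by the planting."""
        out = {lvl: 0.0 for lvl in ("A1", "B1", "A2", "B2", "A3", "B3")}
        cases_per_level: dict[str, set[str]] = {}
        for m in self.matches:
            cases_per_level.setdefault(m.expected_level, set()).add(m.case_id)
        for lvl, cases in cases_per_level.items():
            out[lvl] = len(cases) / self.n_patients if self.n_patients else 0.0
        return out

    def expected_cumulative(self) -> list[float]:
        per_level = self.expected_coverage()
        # Each patient carries at most one planted match, so prefixes add up.
        acc, out = 0.0, []
        for lvl in ("A1", "B1", "A2", "B2", "A3", "B3"):
            acc += per_level[lvl]
            out.append(round(acc, 12))
        return out


def _gene_name(i: int) -> str:
    return f"SYNG{i:03d}"


def generate_kb(
    n_genes: int | None = None,
    tiers_mix: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[list[KnowledgeBaseEntry], dict]:
    """Generate a deterministic miniature knowledge base.

    Covers every variant-specifier kind, both associations, all tiers
    (including an unranked TARGET block), two diseases, and one
    direction-conflicted (gene, drug) pair.  ``tiers_mix`` optionally adds
    extra hotspot entries per tier (name -> count) for stress tests.

    Returns the entry list and a manifest mapping each plantable
    (axis, tier, kind) cell to its gene/drug/descriptor, plus the gene sets
    needed by the cohort generator.
    """
    rng = np.random.default_rng(seed)
    plant_cells = [
        (axis, tier, kind)
        for axis in ("A", "B")
        for tier in _RANKED_TIERS
        for kind in PLANT_KINDS
    ]
    needed = len(plant_cells) + 2 + 1 + 4  # plants + wild-type pair + conflict + TARGET
    if n_genes is None:
        n_genes = needed
    if n_genes < len(VariantKind):
        raise ValueError(
            f"n_genes must be at least {len(VariantKind)} to cover every variant kind"
        )
    genes = [_gene_name(i) for i in range(max(n_genes, needed))]

    entries: list[KnowledgeBaseEntry] = []
    manifest: dict = {
        "diseases": {"A": DISEASE_SAME, "B": DISEASE_OTHER},
        "plants": {},
        "params": {"n_genes": n_genes, "seed": int(seed)},
    }
    gi = 0
    for axis, tier, kind in plant_cells:
        gene = genes[gi]
        gi += 1
        disease = DISEASE_SAME if axis == "A" else DISEASE_OTHER
        drug = f"drug-{axis}-{tier.value}-{kind}".replace("_", "")
        descriptor = ""
        if kind == "exact_hotspot":
            descriptor = f"V{600 + gi}E"
            spec = VariantSpecifier(VariantKind.exact_protein_change, (descriptor,))
        elif kind == "any_missense":
            spec = VariantSpecifier(VariantKind.any_missense)
        elif kind == "stopgain_lof":
            spec = VariantSpecifier(VariantKind.any_inactivating)
        elif kind == "amplification":
            spec = VariantSpecifier(VariantKind.amplification)
        elif kind == "deep_loss":
            spec = VariantSpecifier(VariantKind.deletion)
        else:  # fusion
            descriptor = f"PARTNER{gi:03d}"
            spec = VariantSpecifier(VariantKind.fusion, (descriptor,))
        entries.append(
            KnowledgeBaseEntry(
                source=Source.GDKD,
                gene=gene,
                variant=spec,
                disease=disease,
                drugs=(drug,),
                association=Association.response,
                tier=tier,
                references=(f"SYNREF{gi:03d}",),
            )
        )
        manifest["plants"].setdefault(axis, {}).setdefault(tier.value, {})[kind] = {
            "gene": gene,
            "drug": drug,
            "descriptor": descriptor,
        }

    # Wild-type biomarkers at approved tier in both diseases.
    wt_genes = {}
    for axis, disease in (("A", DISEASE_SAME), ("B", DISEASE_OTHER)):
        gene = genes[gi]
        gi += 1
        wt_genes[axis] = gene
        entries.append(
            KnowledgeBaseEntry(
                source=Source.GDKD,
                gene=gene,
                variant=VariantSpecifier(VariantKind.wild_type),
                disease=disease,
                drugs=(f"drug-wt-{axis}",),
                association=Association.response,
                tier=Tier.approved,
                references=(f"SYNREFWT{axis}",),
            )
        )
    manifest["wildtype_genes"] = wt_genes

    # Direction-conflicted (gene, drug): response and resistance hotspots for
    # the same drug block hotspot repurposing on this gene.
    conflict_gene = genes[gi]
    gi += 1
    conflict_drug = "drug-conflicted"
    for descriptor, association in (("V600E", Association.response), ("V600K", Association.resistance)):
        entries.append(
            KnowledgeBaseEntry(
                source=Source.CIVIC,
                gene=conflict_gene,
                variant=VariantSpecifier(VariantKind.exact_protein_change, (descriptor,)),
                disease=DISEASE_SAME,
                drugs=(conflict_drug,),
                association=association,
                tier=Tier.late_trial,
                references=("SYNREFCONF",),
            )
        )
    manifest["conflict"] = {"gene": conflict_gene, "drug": conflict_drug}

    # Unranked, variant-unspecific TARGET block (gene-level section).
    target_genes = []
    for kind in (
        VariantKind.any_activating,
        VariantKind.any_inactivating,
        VariantKind.amplification,
        VariantKind.fusion,
    ):
        gene = genes[gi]
        gi += 1
        target_genes.append(gene)
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
                drugs=(f"drug-target-{kind.value}".replace("_", ""),),
                association=Association.response,
                tier=Tier.unranked,
            )
        )
    manifest["target_genes"] = target_genes

    for tier_name, count in (tiers_mix or {}).items():
        tier = Tier(tier_name)
        for _ in range(int(count)):
            gene = genes[int(rng.integers(0, len(genes)))]
            descriptor = f"{'ARNDCQEGHILKMFPSTWYV'[int(rng.integers(0, 20))]}{int(rng.integers(1, 900))}A"
            entries.append(
                KnowledgeBaseEntry(
                    source=Source.GDKD,
                    gene=gene,
                    variant=VariantSpecifier(VariantKind.exact_protein_change, (descriptor,)),
                    disease=DISEASE_SAME if rng.integers(0, 2) else DISEASE_OTHER,
                    drugs=(f"drug-extra-{int(rng.integers(0, 10))}",),
                    association=Association.response,
                    tier=tier,
                    references=("SYNREFX",),
                )
            )

    manifest["genes"] = sorted({e.gene for e in entries})
    return entries, manifest


def _level_plan(design: Mapping[str, float], n_patients: int) -> list[str | None]:
    """Assign each patient index a coarse level (or None), deterministically."""
    for lvl, f in design.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"design fraction for {lvl} must be in [0, 1], got {f}")
    if sum(design.values()) > 1.0 + 1e-9:
        raise ValueError("design fractions must sum to at most 1")
    plan: list[str | None] = []
    for lvl in ("A1", "B1", "A2", "B2", "A3", "B3"):
        count = int(round(design.get(lvl, 0.0) * n_patients))
        plan.extend([lvl] * count)
    if len(plan) > n_patients:
        plan = plan[:n_patients]
    plan.extend([None] * (n_patients - len(plan)))
    return plan


def generate_cohort(
    n_patients: int,
    design: Mapping[str, float] | None = None,
    seed: int = 0,
    kb: tuple[list[KnowledgeBaseEntry], dict] | None = None,
) -> tuple[list[PatientProfile], PlantedTruth]:
    """Generate a cohort of patient profiles with planted actionable variants.

    ``design`` maps coarse levels ("A1".."B3", optionally "WT_A1" for
    wild-type findings at A1) to the fraction of patients planted at that
    level; each patient receives at most one planted actionable variant, so
    coverage is exact.  All patients share the knowledge base's axis-A
    disease as cancer type.  Every patient additionally carries distractors
    that must produce no matches: a silent SNV and a low-level CNV in
    knowledge-base genes, and a missense SNV in an off-kb gene.

    ``kb`` is the (entries, manifest) pair from :func:`generate_kb`; omitted,
    a default kb is generated from a seed derived from ``seed``.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    if kb is None:
        kb = generate_kb(seed=(seed * 7919 + 17) % (2**31))
    entries, manifest = kb
    design = dict(DEFAULT_COHORT_DESIGN if design is None else design)
    wt_fraction = design.pop("WT_A1", 0.0)
    if not 0.0 <= wt_fraction <= 1.0:
        raise ValueError("WT_A1 fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    plan = _level_plan(design, n_patients)
    n_wt = int(round(wt_fraction * n_patients))
    plants = manifest["plants"]
    wt_genes = manifest["wildtype_genes"]
    silent_gene = plants["A"][Tier.approved.value]["exact_hotspot"]["gene"]
    lowcnv_gene = plants["A"][Tier.approved.value]["amplification"]["gene"]

    profiles: list[PatientProfile] = []
    truth = PlantedTruth(design={**design, "WT_A1": wt_fraction}, n_patients=n_patients)
    for i in range(n_patients):
        case_id = f"SYN-{i:05d}"
        profile = PatientProfile(case_id=case_id, cancer_type=DISEASE_SAME)
        # Distractors: silent SNV and low-level CNV in kb genes, plus a
        # missense in a gene absent from the kb.
        profile.snvs.append(SNV(silent_gene, SNVClass.silent, f"A{10 + i % 50}A"))
        profile.cnvs.append(CNV(lowcnv_gene, 1 if i % 2 else -1))
        profile.snvs.append(SNV(f"OFFKB{i % 20:02d}", SNVClass.missense, f"G{100 + i % 100}D"))

        wt_planted = i < n_wt
        # Block wild-type biomarkers with benign missense SNVs (no matching
        # entries exist for these genes beyond the wild-type records), except
        # when a wild-type finding is planted for this patient.
        if not wt_planted:
            profile.snvs.append(SNV(wt_genes["A"], SNVClass.missense, "L55F"))
        profile.snvs.append(SNV(wt_genes["B"], SNVClass.missense, "L55F"))
        if wt_planted:
            truth.matches.append(
                PlantedMatch(case_id, wt_genes["A"], "wild_type", "A1", "drug-wt-A")
            )

        level = plan[i]
        if level is not None:
            axis, strength = level[0], level[1]
            tiers = _STRENGTH_TIERS[strength]
            tier = tiers[i % len(tiers)]
            kind = PLANT_KINDS[i % len(PLANT_KINDS)]
            cell = plants[axis][tier.value][kind]
            gene, drug = cell["gene"], cell["drug"]
            if kind == "exact_hotspot":
                profile.snvs.append(SNV(gene, SNVClass.missense, cell["descriptor"]))
                mode = "exact_change"
            elif kind == "any_missense":
                change = f"A{int(rng.integers(2, 999))}V"
                profile.snvs.append(SNV(gene, SNVClass.missense, change))
                mode = "any_missense"
            elif kind == "stopgain_lof":
                profile.snvs.append(SNV(gene, SNVClass.stopgain, f"R{int(rng.integers(2, 999))}X"))
                mode = "repurposed_lof"
            elif kind == "amplification":
                profile.cnvs.append(CNV(gene, 2))
                mode = "type_match"
            elif kind == "deep_loss":
                profile.cnvs.append(CNV(gene, -2))
                mode = "type_match"
            else:  # fusion
                profile.fusions.append(Fusion(gene, cell["descriptor"]))
                mode = "type_match"
            truth.matches.append(PlantedMatch(case_id, gene, mode, level, drug))
        profiles.append(profile)
    return profiles, truth
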