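"""Shared fixtures: a hand-built six-entry knowledge base and patient profile
mirroring a real tumor-board scenario (ovarian carcinoma with a TSC2 stopgain
repurposed onto mTOR-inhibitor loss-of-function evidence), plus random
generators used by the oracle-equivalence tests."""

from __future__ import annotations

import numpy as np
import pytest

from mtbreport.knowledgebase import (
    Association,
    KnowledgeBaseEntry,
    Source,
    Tier,
    VariantKind,
    VariantSpecifier,
)
from mtbreport.patient_io import CNV, Fusion, PatientProfile, SNV, SNVClass


def _entry(gene, kind, disease, drug, association, tier, descriptors=(), source=Source.GDKD, refs=("REF1",)):
    return KnowledgeBaseEntry(
        source=source,
        gene=gene,
        variant=VariantSpecifier(VariantKind(kind), tuple(descriptors)),
        disease=disease,
        drugs=(drug,),
        association=Association(association),
        tier=Tier(tier),
        references=refs if tier != "unranked" else (),
    )


@pytest.fixture
def make_entry():
    return _entry


@pytest.fixture
def master04_kb():
    """Six-entry fixture: ovarian patient with TSC2 R505X stopgain and a
    CCND1 amplification; mTOR-inhibitor evidence dominates."""
    return [
        _entry("TSC2", "any_inactivating", "kidney cancer", "mTOR inhibitor", "response", "late_trial"),
        _entry("TSC2", "any_inactivating", "breast cancer", "mTOR inhibitor", "response", "early_trial"),
        _entry("TSC2", "any_inactivating", "ovarian cancer", "mTOR inhibitor", "response", "preclinical"),
        _entry("CCND1", "amplification", "breast cancer", "CDK4/6 inhibitor", "response", "late_trial"),
        _entry("CCND1", "amplification", "ovarian cancer", "examplinib", "resistance", "case_report"),
        _entry("EGFR", "exact_protein_change", "lung adenocarcinoma", "erlotinib", "response", "approved", ("L858R",)),
    ]


@pytest.fixture
def master04_profile():
    return PatientProfile(
        case_id="MASTER-04-like",
        cancer_type="ovarian cancer",
        snvs=[
            SNV("TSC2", SNVClass.stopgain, "p.R505X"),
            SNV("ACTB", SNVClass.silent, "L10L"),
        ],
        cnvs=[CNV("CCND1", 2), CNV("PTEN", -1)],
        fusions=[],
    )


def random_kb(rng: np.random.Generator, n_entries: int) -> list[KnowledgeBaseEntry]:
    """Random harmonized knowledge base over a small shared gene pool, all
    specifier kinds and tiers represented, with frequent gene/drug collisions
    so that direction consistency is exercised."""
    genes = [f"G{i}" for i in range(12)]
    drugs = [f"d{i}" for i in range(6)]
    diseases = ["alpha cancer", "beta cancer", "gamma cancer"]
    descriptors = ["V600E", "V600K", "G12D", "T790M", "R505X", "L858R"]
    kinds = list(VariantKind)
    tiers = list(Tier)
    entries = []
    for _ in range(n_entries):
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if kind is VariantKind.exact_protein_change:
            k = 1 + int(rng.integers(0, 2))
            desc = tuple(rng.choice(descriptors, size=k, replace=False))
        elif kind is VariantKind.fusion:
            desc = ("any",) if rng.random() < 0.5 else (genes[int(rng.integers(0, len(genes)))],)
        else:
            desc = ()
        tier = tiers[int(rng.integers(0, len(tiers)))]
        entries.append(
            KnowledgeBaseEntry(
                source=Source.GDKD if tier is not Tier.unranked else Source.TARGET,
                gene=genes[int(rng.integers(0, len(genes)))],
                variant=VariantSpecifier(kind, desc),
                disease=diseases[int(rng.integers(0, 3))],
                drugs=(drugs[int(rng.integers(0, len(drugs)))],),
                association=Association.response if rng.random() < 0.7 else Association.resistance,
                tier=tier,
                references=("R",) ,
            )
        )
    return entries


def random_profile(rng: np.random.Generator, case_id: str) -> PatientProfile:
    genes = [f"G{i}" for i in range(12)] + ["OFF1", "OFF2"]
    descriptors = ["V600E", "V600K", "G12D", "T790M", "R505X", "L858R", "A99T"]
    classes = list(SNVClass)
    profile = PatientProfile(case_id=case_id, cancer_type="alpha cancer")
    for _ in range(int(rng.integers(0, 6))):
        profile.snvs.append(
            SNV(
                genes[int(rng.integers(0, len(genes)))],
                classes[int(rng.integers(0, len(classes)))],
                descriptors[int(rng.integers(0, len(descriptors)))],
            )
        )
    for _ in range(int(rng.integers(0, 4))):
        profile.cnvs.append(
            CNV(genes[int(rng.integers(0, len(genes)))], int(rng.integers(-2, 3)))
        )
    for _ in range(int(rng.integers(0, 3))):
        a = genes[int(rng.integers(0, len(genes)))]
        b = genes[int(rng.integers(0, len(genes)))]
        if a != b:
            profile.fusions.append(Fusion(a, b))
    return profile
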