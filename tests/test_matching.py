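"""Matching flowchart: central path, repurposing side arms, wild type."""

import numpy as np
import pytest

from conftest import random_kb, random_profile
from oracle_matcher import naive_match_profile

from mtbreport.knowledgebase import Tier, VariantKind, aggregate_entries
from mtbreport.matching import (
    MatchMode,
    MatchRecord,
    direction_consistent,
    match_cnv,
    match_fusion,
    match_profile,
    match_snv,
    match_wildtype,
)
from mtbreport.patient_io import CNV, Fusion, PatientProfile, SNV, SNVClass


class TestMatchSnv:
    def test_stopgain_repurposed_as_loss_of_function(self, make_entry):
        """A stopgain in a gene with loss-of-function entries is repurposed
        (unknown significance), the TSC2/mTOR-inhibitor scenario."""
        kb = [make_entry("TSC2", "any_inactivating", "kidney cancer",
                         "everolimus", "response", "late_trial")]
        records = match_snv(SNV("TSC2", SNVClass.stopgain, "R505X"), kb)
        assert len(records) == 1
        assert records[0].match_mode is MatchMode.repurposed_lof
        assert records[0].known_significance is False

    def test_exact_hotspot_containment(self, make_entry):
        kb = [make_entry("BRAF", "exact_protein_change", "melanoma",
                         "vemurafenib", "response", "approved", ("V600E",))]
        records = match_snv(SNV("BRAF", SNVClass.missense, "V600E"), kb)
        assert [r.match_mode for r in records] == [MatchMode.exact_change]
        assert records[0].known_significance

    def test_no_fusion_to_missense_repurposing(self, make_entry):
        """A missense mutation never matches fusion-only entries for the
        same gene (too many false positives otherwise)."""
        kb = [make_entry("NTRK3", "fusion", "sarcoma", "lestaurtinib",
                         "response", "early_trial", ("ETV6",))]
        assert match_snv(SNV("NTRK3", SNVClass.missense, "R116W"), kb) == []

    def test_any_missense_entry(self, make_entry):
        kb = [make_entry("EGFR", "any_missense", "lung adenocarcinoma",
                         "erlotinib", "response", "early_trial")]
        records = match_snv(SNV("EGFR", SNVClass.missense, "A289V"), kb)
        assert [r.match_mode for r in records] == [MatchMode.any_missense]
        # a stopgain is not a missense mutation
        assert match_snv(SNV("EGFR", SNVClass.stopgain, "R100X"), kb) == []

    def test_silent_never_matches(self, make_entry):
        kb = [make_entry("BRAF", "any_missense", "melanoma", "vemurafenib",
                         "response", "approved")]
        assert match_snv(SNV("BRAF", SNVClass.silent, "V600V"), kb) == []

    def test_hotspot_repurposing_requires_direction_consistency(self, make_entry):
        consistent = [
            make_entry("KIT", "exact_protein_change", "GIST", "imatinib",
                       "response", "approved", ("V559D",)),
            make_entry("KIT", "exact_protein_change", "GIST", "imatinib",
                       "response", "late_trial", ("W557G",)),
        ]
        records = match_snv(SNV("KIT", SNVClass.missense, "A837T"), consistent)
        assert {r.match_mode for r in records} == {MatchMode.repurposed_hotspot}
        assert all(not r.known_significance for r in records)

        conflicted = consistent + [
            make_entry("KIT", "exact_protein_change", "GIST", "imatinib",
                       "resistance", "approved", ("D816V",))
        ]
        vus = match_snv(SNV("KIT", SNVClass.missense, "A837T"), conflicted)
        assert vus == []
        # exact containment is unaffected by the conflict
        exact = match_snv(SNV("KIT", SNVClass.missense, "D816V"), conflicted)
        assert [r.match_mode for r in exact] == [MatchMode.exact_change]

    def test_indel_with_descriptor_matches_exact_not_any_missense(self, make_entry):
        kb = [
            make_entry("EGFR", "exact_protein_change", "lung adenocarcinoma",
                       "erlotinib", "response", "approved", ("745-750DEL",)),
            make_entry("EGFR", "any_missense", "lung adenocarcinoma",
                       "gefitinib", "response", "early_trial"),
        ]
        records = match_snv(SNV("EGFR", SNVClass.inframe_indel, "745-750del"), kb)
        assert [r.match_mode for r in records] == [MatchMode.exact_change]


class TestMatchCnv:
    def test_high_amplification(self, make_entry):
        kb = [make_entry("ERBB2", "amplification", "breast cancer",
                         "trastuzumab", "response", "approved")]
        records = match_cnv(CNV("ERBB2", 2), kb)
        assert [r.match_mode for r in records] == [MatchMode.type_match]

    def test_low_level_gain_never_matches(self, make_entry):
        kb = [make_entry("ERBB2", "amplification", "breast cancer",
                         "trastuzumab", "response", "approved")]
        assert match_cnv(CNV("ERBB2", 1), kb) == []

    def test_deep_loss_matches_inactivating(self, make_entry):
        kb = [make_entry("BRCA2", "any_inactivating", "ovarian cancer",
                         "PARP inhibitors", "response", "late_trial")]
        records = match_cnv(CNV("BRCA2", -2), kb)
        assert [r.match_mode for r in records] == [MatchMode.type_match]

    def test_cnv_never_matches_hotspot_or_missense_entries(self, make_entry):
        kb = [
            make_entry("EGFR", "exact_protein_change", "lung adenocarcinoma",
                       "erlotinib", "response", "approved", ("L858R",)),
            make_entry("EGFR", "any_missense", "lung adenocarcinoma",
                       "gefitinib", "response", "early_trial"),
        ]
        assert match_cnv(CNV("EGFR", 2), kb) == []
        assert match_cnv(CNV("EGFR", -2), kb) == []


class TestMatchFusion:
    def test_named_partner(self, make_entry):
        kb = [make_entry("ABL1", "fusion", "chronic myeloid leukemia",
                         "imatinib", "response", "approved", ("BCR",))]
        assert len(match_fusion(Fusion("BCR", "ABL1"), kb)) == 1
        assert match_fusion(Fusion("ETV6", "ABL1"), kb) == []

    def test_any_partner(self, make_entry):
        kb = [make_entry("ALK", "fusion", "lung adenocarcinoma",
                         "crizotinib", "response", "approved", ("any",))]
        assert len(match_fusion(Fusion("EML4", "ALK"), kb)) == 1
        assert len(match_fusion(Fusion("ALK", "XYZ"), kb)) == 1

    def test_empty_kb(self):
        assert match_fusion(Fusion("A1", "B1"), []) == []


class TestMatchWildtype:
    def test_wildtype_biomarker(self, make_entry):
        kb = [make_entry("KRAS", "wild_type", "colorectal cancer",
                         "cetuximab", "response", "approved")]
        profile = PatientProfile("p1", "colorectal cancer",
                                 snvs=[SNV("TP53", SNVClass.missense, "R175H")])
        records = match_wildtype(profile, kb)
        assert [r.match_mode for r in records] == [MatchMode.wild_type]
        assert records[0].known_significance

    def test_altered_gene_blocks_wildtype(self, make_entry):
        kb = [make_entry("KRAS", "wild_type", "colorectal cancer",
                         "cetuximab", "response", "approved")]
        profile = PatientProfile("p1", "colorectal cancer",
                                 snvs=[SNV("KRAS", SNVClass.missense, "G12D")])
        assert match_wildtype(profile, kb) == []
        # a silent KRAS variant does not count as altered
        silent = PatientProfile("p2", "colorectal cancer",
                                snvs=[SNV("KRAS", SNVClass.silent, "G12G")])
        assert len(match_wildtype(silent, kb)) == 1

    def test_matches_equal_set_difference(self, make_entry):
        genes = [f"G{i}" for i in range(20)]
        kb = [make_entry(g, "wild_type", "alpha cancer", "drugX",
                         "response", "approved") for g in genes]
        altered = genes[::3]
        profile = PatientProfile(
            "p", "alpha cancer",
            snvs=[SNV(g, SNVClass.missense, "A5V") for g in altered],
        )
        records = match_wildtype(profile, kb)
        assert {r.entry.gene for r in records} == set(genes) - set(altered)


class TestDirectionConsistent:
    def test_all_same_direction(self, make_entry):
        kb = [make_entry("KIT", "exact_protein_change", "GIST", "imatinib",
                         "response", t, (d,))
              for t, d in [("approved", "V559D"), ("late_trial", "W557G"),
                           ("preclinical", "L576P")]]
        assert direction_consistent("KIT", "imatinib", kb)

    def test_conflict(self, make_entry):
        kb = [
            make_entry("KIT", "exact_protein_change", "GIST", "imatinib",
                       "response", "approved", ("V559D",)),
            make_entry("KIT", "exact_protein_change", "GIST", "imatinib",
                       "resistance", "approved", ("D816V",)),
        ]
        assert not direction_consistent("KIT", "imatinib", kb)

    def test_vacuously_false_without_entries(self):
        assert not direction_consistent("KIT", "imatinib", [])

    def test_equals_brute_force_all_equal_check(self):
        rng = np.random.default_rng(11)
        kb = random_kb(rng, 80)
        for gene in {e.gene for e in kb}:
            for drug in {d for e in kb for d in e.drugs}:
                directions = {e.association for e in kb
                              if e.gene == gene and drug in e.drugs}
                assert direction_consistent(gene, drug, kb) == (len(directions) == 1)


class TestMatchProfile:
    def test_empty_profile(self, make_entry):
        kb = [make_entry("BRAF", "exact_protein_change", "melanoma",
                         "vemurafenib", "response", "approved", ("V600E",))]
        assert match_profile(PatientProfile("p", "melanoma"), kb) == []

    def test_duplicate_variant_deduplicated(self, make_entry):
        kb = [make_entry("BRAF", "exact_protein_change", "melanoma",
                         "vemurafenib", "response", "approved", ("V600E",))]
        snv = SNV("BRAF", SNVClass.missense, "V600E")
        profile = PatientProfile("p", "melanoma", snvs=[snv, snv])
        assert len(match_profile(profile, kb)) == 1

    def test_master04_like_fixture(self, master04_profile, master04_kb):
        records = match_profile(master04_profile, master04_kb)
        tsc2 = [r for r in records if r.gene == "TSC2"]
        assert len(tsc2) == 3
        assert all(r.match_mode is MatchMode.repurposed_lof for r in tsc2)
        assert all("mTOR inhibitor" in r.entry.drugs for r in tsc2)

    def test_deterministic_order(self):
        rng = np.random.default_rng(3)
        kb = aggregate_entries(random_kb(rng, 100))
        profile = random_profile(np.random.default_rng(4), "p")
        assert match_profile(profile, kb) == match_profile(profile, kb)


def _as_triples(records):
    return {(r.patient_variant, r.entry, r.match_mode.value) for r in records}


class TestOracleEquivalence:
    def test_matcher_equals_naive_scan(self):
        """The matcher agrees with a literal nested-loop transcription of
        the filtering flowchart on randomized knowledge bases and profiles."""
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            kb = aggregate_entries(random_kb(rng, 100))
            for i in range(10):
                profile = random_profile(rng, f"case{i}")
                got = _as_triples(match_profile(profile, kb))
                expected = naive_match_profile(profile, kb)
                assert got == expected

    def test_silent_and_low_cnv_contribute_nothing(self):
        rng = np.random.default_rng(5)
        kb = aggregate_entries(random_kb(rng, 120))
        for i in range(20):
            profile = random_profile(rng, f"c{i}")
            profile.snvs = [SNV(s.gene, SNVClass.silent, s.protein_change)
                            for s in profile.snvs]
            profile.cnvs = [CNV(c.gene, max(-1, min(1, c.gistic_value)))
                            for c in profile.cnvs]
            profile.fusions = []
            records = match_profile(profile, kb)
            assert all(r.match_mode is MatchMode.wild_type for r in records)

    def test_repurposed_hotspot_implies_direction_consistency(self):
        rng = np.random.default_rng(6)
        kb = aggregate_entries(random_kb(rng, 150))
        for i in range(20):
            profile = random_profile(rng, f"c{i}")
            for r in match_profile(profile, kb):
                if r.match_mode is MatchMode.repurposed_hotspot:
                    for drug in r.entry.drugs:
                        assert direction_consistent(r.gene, drug, kb)


class TestMonotonicity:
    def test_adding_entries_never_removes_nonhotspot_records(self, make_entry):
        rng = np.random.default_rng(8)
        kb = aggregate_entries(random_kb(rng, 80))
        extra = make_entry("G0", "any_missense", "alpha cancer", "dnew",
                           "response", "late_trial")
        for i in range(10):
            profile = random_profile(rng, f"c{i}")
            before = _as_triples(match_profile(profile, kb))
            after = _as_triples(match_profile(profile, kb + [extra]))
            lost = before - after
            assert all(mode == "repurposed_hotspot" for (_, _, mode) in lost)

    def test_conflicting_entry_removes_only_hotspot_repurposing(self, make_entry):
        kb = [
            make_entry("KIT", "exact_protein_change", "GIST", "imatinib",
                       "response", "approved", ("V559D",)),
            make_entry("KIT", "any_inactivating", "GIST", "imatinib",
                       "response", "late_trial"),
        ]
        profile = PatientProfile(
            "p", "GIST",
            snvs=[SNV("KIT", SNVClass.missense, "A837T"),
                  SNV("KIT", SNVClass.stopgain, "R100X")],
        )
        before = _as_triples(match_profile(profile, kb))
        conflict = make_entry("KIT", "exact_protein_change", "GIST", "imatinib",
                              "resistance", "approved", ("D816V",))
        after = _as_triples(match_profile(profile, kb + [conflict]))
        lost = before - after
        assert lost and all(mode == "repurposed_hotspot" for (_, _, mode) in lost)
        # the loss-of-function repurposing is untouched
        assert any(mode == "repurposed_lof" for (_, _, mode) in after)


def test_match_record_significance_invariant(make_entry):
    entry = make_entry("BRAF", "exact_protein_change", "melanoma",
                       "vemurafenib", "response", "approved", ("V600E",))
    snv = SNV("BRAF", SNVClass.missense, "V600E")
    with pytest.raises(ValueError):
        MatchRecord(snv, entry, MatchMode.repurposed_hotspot, True)
    with pytest.raises(ValueError):
        MatchRecord(snv, entry, MatchMode.exact_change, False)
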