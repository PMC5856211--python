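"""Independent brute-force reference matcher used as a test oracle.

A literal O(V x E) nested-loop transcription of the filtering flowchart:
gene level first, then variant type, then protein change, with the two
repurposing side arms (direction-consistent hotspots; stopgain/frameshift/
splice onto loss-of-function entries) and the wild-type branch.  No
indexing, no shared helpers with the implementation under test.
"""

from __future__ import annotations

MISSENSE_LIKE = {"missense", "inframe_indel", "stoploss", "other"}
LOF = {"stopgain", "frameshift_indel", "splice"}


def _directions(kb, gene, drug):
    return {e.association.value for e in kb if e.gene == gene and drug in e.drugs}


def _snv_mode(snv, entry, kb):
    kind = entry.variant.kind.value
    cls = snv.classification.value
    if kind == "exact_protein_change":
        if snv.protein_change and snv.protein_change in entry.variant.descriptors:
            return "exact_change"
        if cls in MISSENSE_LIKE and all(
            len(_directions(kb, entry.gene, d)) == 1 for d in entry.drugs
        ):
            return "repurposed_hotspot"
        return None
    if kind == "any_missense":
        return "any_missense" if cls == "missense" else None
    if kind in ("any_inactivating", "deletion"):
        if cls in LOF:
            return "repurposed_lof"
        if entry.tier.value == "unranked":
            return "type_match"
        return None
    if kind == "any_activating":
        return "type_match" if entry.tier.value == "unranked" else None
    return None


def naive_match_profile(profile, kb):
    """Return the set of (patient_variant, entry, mode-name) triples."""
    out = set()
    for snv in profile.snvs:
        if snv.classification.value == "silent":
            continue
        for entry in kb:
            if entry.gene != snv.gene:
                continue
            mode = _snv_mode(snv, entry, kb)
            if mode is not None:
                out.add((snv, entry, mode))
    for cnv in profile.cnvs:
        if cnv.gistic_value == 2:
            wanted = ("amplification", "any_activating")
        elif cnv.gistic_value == -2:
            wanted = ("deletion", "any_inactivating")
        else:
            continue
        for entry in kb:
            if entry.gene == cnv.gene and entry.variant.kind.value in wanted:
                out.add((cnv, entry, "type_match"))
    for fusion in profile.fusions:
        for entry in kb:
            if entry.variant.kind.value != "fusion":
                continue
            for this, other in (
                (fusion.gene5p, fusion.gene3p),
                (fusion.gene3p, fusion.gene5p),
            ):
                if entry.gene == this and (
                    "any" in entry.variant.descriptors
                    or other in entry.variant.descriptors
                ):
                    out.add((fusion, entry, "type_match"))
                    break
    altered = set()
    for snv in profile.snvs:
        if snv.classification.value != "silent":
            altered.add(snv.gene)
    for cnv in profile.cnvs:
        if abs(cnv.gistic_value) == 2:
            altered.add(cnv.gene)
    for fusion in profile.fusions:
        altered.add(fusion.gene5p)
        altered.add(fusion.gene3p)
    for entry in kb:
        if entry.variant.kind.value == "wild_type" and entry.gene not in altered:
            out.add((entry.gene, entry, "wild_type"))
    return out
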