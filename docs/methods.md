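# Methods

This note documents the models and procedures implemented in `mtbreport`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limitations of the synthetic-data evaluation.

## Knowledge-base harmonization

Three public predictive-biomarker databases are parsed into one schema
(`KnowledgeBaseEntry`): GDKD, CIViC and TARGET, plus an optional
expert-rules table already in the harmonized layout. Column layouts differ
across export versions, so every loader takes a configurable column map;
the defaults model the public exports. Vocabulary harmonization:

| concept | GDKD | CIViC | TARGET | harmonized |
|---|---|---|---|---|
| association | response / resistance &c. | Sensitivity / "Resistance or non-response" | — (free text) | `response` / `resistance` |
| evidence | NCCN/FDA, Late trials, Early trials, Case report, Preclinical | A–E | none | `approved`, `late_trial`, `early_trial`, `case_report`, `preclinical`, `unranked` |

Decisions taken here:

* **CIViC level A → `approved`** (CIViC calls it "clinical routine") and
  **level E is dropped**: the tier ladder bottoms out at preclinical
  evidence, and inferential evidence falls below that floor. Both are
  override-able via the vocabulary maps.
* **CIViC non-predictive rows** (prognostic, diagnostic) are excluded.
* **TARGET entries are `unranked`**: the database is not variant-specific
  and carries no evidence levels or references, so its hits are reported in
  a separate gene-level section and never placed on the A1–B3 ladder.
  TARGET alteration free text resolves through a keyword map; unrecognized
  text skips the row rather than guessing a kind.
* **Aggregation** merges entries identical on (source, gene, disease,
  drugs, tier, association, variant kind) with the union of descriptors and
  references. The variant kind participates in the key — merging a hotspot
  list with an "any missense" annotation would make the descriptor set
  ill-typed. Aggregation is idempotent and order-deterministic.
* **Protein changes** normalize by stripping the `p.` prefix, converting
  three-letter amino-acid codes to one-letter (Ter/\* → X), removing
  whitespace and uppercasing. Matching compares normalized forms only.
* **Disease labels** harmonize through a case-insensitive synonym table
  shipped with the package and extensible via config; unmapped labels pass
  through verbatim with a log flag. "Same cancer type" downstream is exact
  equality of harmonized labels — no ontology ancestry — so the synonym
  table is the single auditable place where entity equivalence is decided.
* GDKD's consensus/emerging annotation is not used: it has no counterpart
  in the other sources and no role in the level assignment.

## Patient input

SNV/indel tables are tab-delimited with MAF-compatible default column
names; silent variants are read and flagged rather than dropped so QC
totals can report them, but they never reach matching. CNVs come from a
GISTIC 2.0 `all_thresholded.by_genes` matrix; only high-level events
(value ±2, approximating homozygous events) are actionable. Fusions are
two-column rows or `GENE1-GENE2` strings with partner order preserved.
Gene symbols are taken as-is (no HGNC alias resolution — an acknowledged
limitation); coordinates are never interpreted.

## Matching

Matching is gene-symbol + variant-type + protein-change based, per the
flowchart: central path first (exact protein-change containment, or "any
missense" entries for missense SNVs), then repurposing side arms for
variants of unknown significance:

* **Hotspot repurposing** requires direction consistency: every entry for
  the (gene, drug) pair in the merged, aggregated knowledge base must share
  one association direction; it is vacuously false with no entries.
  Eligible SNV classes are missense, in-frame indel, stoploss (treated like
  missense, no stated convention exists) and unclassifiable; stopgain,
  frameshift and splice variants instead take the loss-of-function arm.
* **Loss-of-function repurposing** matches stopgain/frameshift/splice SNVs
  to `any_inactivating` and `deletion` entries. Splice sites are included
  by convention (configurable in spirit; they are flagged by their match
  mode and variant class in every output). Both repurposed modes carry
  `known_significance = False` and render gray/"repurposed".
* CNVs: +2 matches amplification/gain-of-function entries, −2 matches
  deletion/loss-of-function entries; CNVs never match hotspot or
  any-missense entries and are never repurposed. Deep losses do not
  repurpose onto hotspot entries (no supporting precedent; not done).
* Fusions match fusion entries on either partner; a named partner
  descriptor must equal the other partner; `any` matches all. Fusions are
  never repurposed into missense matches, and indels with protein
  descriptors do not match "any missense" entries (they are not missense).
* Ranked (GDKD/CIViC/expert) `any_activating` entries are not matched by
  SNVs at all: an unlisted point mutation cannot be asserted to activate.
  Unranked TARGET `any_activating`/`any_inactivating` entries, being
  variant-unspecific by design, are hit gene-level by any non-silent SNV
  and routed to the report's TARGET section.
* When one variant matches one entry through several modes, the strongest
  is kept (exact > any-missense > type > repurposed); duplicates on
  (variant, entry) are removed and output order is deterministic.

The matcher is validated against an independent, literal nested-loop
implementation of the flowchart on randomized inputs (oracle equivalence),
and against planted synthetic cohorts (sensitivity 1.0, zero matches on
genes absent from the knowledge base).

## Evidence levels and report

Axis A/B is same/other cancer type (exact harmonized-label equality);
strength 1/2a/2b/2c/3 follows the tier. The total order is
A1 < B1 < A2a < A2b < A2c < B2a < B2b < B2c < A3 < B3; unranked sorts last.
Cumulative statistics use the six coarse levels (sub-ranks affect only
within-level sorting and breakdowns). Exact label equality can under-rank
evidence whose entity vocabulary differs from the patient label (e.g. an
approved-in-lung drug reported at B2 for a pulmonary adenocarcinoma when
the labels do not unify); extending the synonym table is the remedy, and
the behavior is deliberate rather than ontology-guessing.

Report rows expand one per (match, drug). Ranking: (1) per-drug response
row count, descending — "drug support" counts response rows only, so
resistance rows sort after response rows within their drug's block;
(2) evidence level; (3) gene. `drug_support` is 100 × response rows for the
drug / total ranked rows, to one decimal. Known published per-case tables
contain a few drug-support values that are not integer row fractions under
this definition; those denominators are not reconstructable and were not
force-fit. Rendering (markdown/HTML/CSV) is byte-deterministic; response is
green, resistance red, unknown significance gray/"repurposed".

## Cohort statistics

The molecular status matrix uses four mutually exclusive categories (wild
type, mutated, high-level amplification, deep loss) over an
actionable-gene list; genes unaltered in every sample are removed. When a
gene has both a non-silent SNV and a high-level CNV in one sample, the SNV
wins (mutation is the more specific annotation; the conflict is logged).
Coverage counts a patient at level L given ≥1 response association at L
from a non-wild-type match, with the A1 exception keeping wild-type and
resistance findings; the same exclusion applies to the genes-per-patient
statistic (mean ± population SD over the patients counted at that level).
Unranked TARGET hits never contribute. Percentages print to one decimal.

## Synthetic data

`generate_kb` lays out a deterministic grid: one entry per (axis, tier,
plantable-scenario) cell with a unique gene and drug per cell, wild-type
biomarkers in both diseases, one direction-conflicted (gene, drug) hotspot
pair, and an unranked TARGET block — every specifier kind, tier and
association occurs. `generate_cohort` assigns each patient at most one
planted actionable variant according to per-level design fractions
(deterministic assignment, so coverage is exact), cycling through the six
scenarios (exact hotspot, any-missense, stopgain→LoF, ±2 CNV, fusion) and
the level-2 sub-tiers. Every patient also carries distractors that must
not match: a silent SNV and a low-level CNV in knowledge-base genes, and a
missense SNV in a gene absent from the knowledge base. Wild-type
biomarker genes are blocked with benign missense SNVs except in patients
designated for a wild-type finding, so wild-type matches are planted
exactly too.

The default design plants per-level increments whose cumulative sums are
9.9 / 22.7 / 64.1 / 89.0 / 90.6 / 94.0 percent — the actionability profile
reported for an exome-wide pan-cancer cohort — at n = 1000 patients, where
all fractions are exact. The acceptance script measures these numbers
end-to-end through the pipeline.

What the synthetic cohort does *not* emulate: realistic mutation burdens
and signatures, gene-symbol aliasing, multi-drug entries with conflicting
directions in real proportions, panel-vs-exome ascertainment differences,
and free-text disease vocabulary noise. Passing the planted-recovery tests
therefore demonstrates the correctness of the filtering/classification
logic, not real-data coverage numbers; those depend on the pinned database
exports and cohort inputs, which users can stage locally (see the
external-reproduction test) but are not bundled.

## Numerical and degenerate-input choices

* Empty inputs are legal everywhere: empty files with valid headers load
  to empty lists; empty reports render header-only CSV; empty cohorts give
  zero coverage.
* Ties in ranking break by drug name, gene, variant text and source, so
  output is stable across runs and platforms.
* Rounding uses Python's `round` at one decimal only at the display /
  serialization boundary; internal fractions are exact.
* Seeds: all generators take explicit seeds; derived seeds stay below 2^31.
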