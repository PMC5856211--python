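# mtbreport

Evidence-driven reporting of actionable somatic variants for molecular
tumor boards (MTBs).

Interpreting a tumor's somatic variants — SNVs and indels, copy-number
variants (CNVs), and gene fusions — against the growing literature on
predictive biomarkers is a major bottleneck for precision oncology.
`mtbreport` automates the filtering step: it harmonizes public knowledge
bases of gene–drug predictive associations, matches a patient's variants
against them (including conservative *repurposing* rules for variants of
unknown significance), classifies every variant–drug association into a
six-level evidence system, and emits a ranked per-patient report plus
cohort-level actionability statistics. It is aimed at bioinformaticians
and clinician-scientists preparing MTB discussions; it pre-filters and
organizes evidence, it does not make treatment decisions.

## The model

**Knowledge bases.** Three public databases are harmonized into one schema:
GDKD (Gene Drug Knowledge Database), CIViC (Clinical Interpretation of
Variants in Cancer) and TARGET (Tumor Alterations Relevant for
Genomics-driven Therapy), plus an optional expert-rules table. Only
*predictive* biomarkers are used. Evidence vocabularies map onto a common
tier (approved > late trials > early trials > case report > preclinical);
TARGET provides no evidence levels and no variant specifics, so its entries
stay unranked and are reported gene-level only. Entries in the same gene
sharing disease, drug, tier and association direction are aggregated into a
single entry with the union of variant descriptors.

**Matching.** Variants are queried gene-first, then by variant type, then —
for SNVs — by protein change. A variant that fails the central path is of
unknown significance and two repurposing side arms apply:

* an unknown-significance SNV matches the gene's *hotspot* entries only if
  every association between that gene and the drug in the database points
  in the same direction (always response, or always resistance);
* a stopgain/frameshift/splice mutation matches the gene's copy-number-loss
  / loss-of-function entries.

CNVs are actionable only at GISTIC's high-level thresholds (±2); fusions
match fusion entries on either partner; fusions are never repurposed into
missense matches. Wild-type biomarkers (e.g. *KRAS* wild type → anti-EGFR
response in colorectal cancer) match when the gene carries no alteration.

**Evidence levels.** Each association is placed on two axes: cancer type
(**A** = evidence in the patient's cancer type, **B** = any other) and
evidence strength (**1** approved / guidelines; **2** clinical — late
trials **2a** > early trials **2b** > case reports **2c**; **3**
preclinical). Report rows are ranked by drug support (number of response
rows per drug), then by level (A1 > B1 > A2 > B2 > A3 > B3), then by gene,
keeping each drug's rows contiguous. Cohort statistics report the fraction
of patients with at least one qualifying association per level and
cumulatively from A1 to B3; wild-type and resistance findings are excluded
there, except at A1 where they are clinically decisive.

## Worked example

An ovarian-carcinoma patient with a *TSC2* stopgain (R505X) and a *CCND1*
high-level amplification, against a six-entry knowledge base with
mTOR-inhibitor evidence for *TSC2* loss of function:

```python
from mtbreport import (SNV, CNV, SNVClass, PatientProfile,
                       match_profile, build_report, drug_support, render_report)
# kb: six harmonized entries (see tests/conftest.py::master04_kb)
profile = PatientProfile("MASTER-04-like", "ovarian cancer",
    snvs=[SNV("TSC2", SNVClass.stopgain, "p.R505X"),
          SNV("ACTB", SNVClass.silent, "L10L")],
    cnvs=[CNV("CCND1", 2), CNV("PTEN", -1)])
report = build_report(profile, match_profile(profile, kb))
print(report.level_counts)   # {'A2': 1, 'B2': 3, 'A3': 1}
print(drug_support(report))  # {'CDK4/6 inhibitor': 20.0, 'examplinib': 0.0,
                             #  'mTOR inhibitor': 60.0}
```

The stopgain is not in any database, but the loss-of-function side arm
repurposes it onto the *TSC2* "loss-of-function → mTOR inhibitor" entries:
the report's first-ranked block is the mTOR inhibitor (3 of 5 rows, drug
support 60.0%), led by a level-B2 row flagged gray/`repurposed` (evidence
from another entity, clinical-trial strength). The silent SNV and the
low-level *PTEN* loss contribute nothing. The full rendered report is in
`tests/data/master04_report.md`.

A command-line interface wraps the same pipeline:

```bash
mtb-report run --snv snv.maf --cnv all_thresholded.by_genes.txt \
    --cancer-type "ovarian carcinoma" --kb kb_dir/ --out reports/
mtb-report cohort --profiles cohort_dir/ --kb kb_dir/ --out stats/
mtb-report synth --kb-out kb_dir/ --cohort-out cohort_dir/ --n-patients 100 --seed 1
```

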