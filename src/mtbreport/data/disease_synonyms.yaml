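# Cancer-type synonym table: raw label (case-insensitive) -> canonical label.
# Extend via the `disease_synonyms` key of the YAML config.
Breast: breast cancer
Breast carcinoma: breast cancer
BRCA: breast cancer
Bladder: bladder cancer
BLCA: bladder cancer
Uterine: uterine cancer
UCEC: uterine cancer
Rectal: rectal cancer
READ: rectal cancer
Colon: colon cancer
COAD: colon cancer
Colorectal: colorectal cancer
Colorectal carcinoma: colorectal cancer
Ovarian: ovarian cancer
Ovarian carcinoma: ovarian cancer
OV: ovarian cancer
Lung squamous carcinoma: lung squamous cancer
LUSC: lung squamous cancer
Lung adenocarcinoma: lung adenocarcinoma
Pulmonary adenocarcinoma: lung adenocarcinoma
LUAD: lung adenocarcinoma
Acute myeloid leukaemia: acute myeloid leukemia
Acute myeloid leukemia: acute myeloid leukemia
LAML: acute myeloid leukemia
AML: acute myeloid leukemia
Kidney: kidney cancer
Renal: kidney cancer
Renal cell carcinoma: kidney cancer
KIRC: kidney cancer
Head and neck: head and neck cancer
HNSC: head and neck cancer
Glioblastoma: glioblastoma multiforme
GBM: glioblastoma multiforme
Melanoma: melanoma
Skin cutaneous melanoma: melanoma
Gastric: gastric cancer
Stomach: gastric cancer
Pancreatic: pancreatic cancer
Pancreatic adenocarcinoma: pancreatic cancer
Prostate: prostate cancer
Cholangiocarcinoma: cholangiocarcinoma
Chronic myeloid leukemia: chronic myeloid leukemia
CML: chronic myeloid leukemia
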