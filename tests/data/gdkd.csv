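Gene,Variant,Disease,Drug,Association,Evidence level,References
TSC2,loss-of-function,renal cell carcinoma,everolimus,response,Late trials,PMID:1
BRAF,V600E,melanoma,vemurafenib,response,NCCN/FDA,PMID:2
BRAF,V600K,melanoma,vemurafenib,response,NCCN/FDA,PMID:3
EGFR,any missense mutation,lung adenocarcinoma,erlotinib,response,Early trials,PMID:4
KRAS,wild type,colorectal cancer,cetuximab,response,NCCN/FDA,PMID:5
ERBB2,amplification,breast cancer,trastuzumab,response,NCCN/FDA,PMID:6
CDKN2A,copy number loss,melanoma,palbociclib,response,Preclinical,PMID:7
ABL1,BCR-ABL1 fusion,chronic myeloid leukemia,imatinib,response,NCCN/FDA,PMID:8
KIT,activating mutation,gastrointestinal stromal tumor,imatinib,response,Case report,PMID:9
EGFR,T790 M,lung adenocarcinoma,erlotinib,resistance,NCCN/FDA,PMID:10
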