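gene,variant,disease,drugs,evidence_type,evidence_level,clinical_significance,citation_id
BRAF,V600E,Melanoma,Vemurafenib,Predictive,A,Sensitivity,100
EGFR,L858R,Lung Adenocarcinoma,Erlotinib,Predictive,A,Sensitivity,101
EGFR,T790M,Lung Adenocarcinoma,Erlotinib,Predictive,B,Resistance,102
KRAS,G12D,Colorectal Cancer,Cetuximab,Predictive,B,Resistance or non-response,103
TP53,R175H,Breast Cancer,,Prognostic,B,Poor Outcome,104
PIK3CA,E545K,Breast Cancer,Alpelisib,Predictive,C,Sensitivity,105
PTEN,loss-of-function,Prostate Cancer,AZD8186,Predictive,D,Sensitivity,106
NRAS,Q61K,Melanoma,Binimetinib,Predictive,E,Sensitivity,107
ERBB2,amplification,Gastric Cancer,Trastuzumab,Predictive,B,Sensitivity,108
ALK,EML4-ALK fusion,Lung Adenocarcinoma,Crizotinib,Predictive,B,Sensitivity,109
MET,amplification,Lung Adenocarcinoma,Crizotinib,Predictive,C,Sensitivity,110
BRCA1,mutation,Ovarian Cancer,Olaparib,Predictive,D,Sensitivity,111
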