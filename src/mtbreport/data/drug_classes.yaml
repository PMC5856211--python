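# Optional drug -> drug-class table, used for display grouping only.
everolimus: mTOR inhibitor
temsirolimus: mTOR inhibitor
rapamycin: mTOR inhibitor
vemurafenib: BRAF inhibitor
dabrafenib: BRAF inhibitor
trametinib: MEK inhibitor
selumetinib: MEK inhibitor
erlotinib: EGFR inhibitor
gefitinib: EGFR inhibitor
afatinib: EGFR inhibitor
osimertinib: EGFR inhibitor
cetuximab: anti-EGFR antibody
panitumumab: anti-EGFR antibody
trastuzumab: HER2 inhibitor
lapatinib: HER2 inhibitor
pertuzumab: HER2 inhibitor
olaparib: PARP inhibitor
rucaparib: PARP inhibitor
niraparib: PARP inhibitor
imatinib: BCR-ABL inhibitor
dasatinib: BCR-ABL inhibitor
nilotinib: BCR-ABL inhibitor
bosutinib: BCR-ABL inhibitor
ponatinib: BCR-ABL inhibitor
palbociclib: CDK4/6 inhibitor
ribociclib: CDK4/6 inhibitor
abemaciclib: CDK4/6 inhibitor
crizotinib: ALK inhibitor
alectinib: ALK inhibitor
sorafenib: multikinase inhibitor
sunitinib: multikinase inhibitor
pazopanib: multikinase inhibitor
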