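Gene,Types of alterations,Therapeutic agents
CDKN2A,Deletion,CDK4/6 inhibitors
BRAF,Mutation,Vemurafenib
ERBB2,Amplification,Trastuzumab
ALK,"Rearrangement, Mutation",Crizotinib
MYSTERY,Chromothripsis,Somedrugib
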