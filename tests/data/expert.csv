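gene,variant_kind,variant_descriptor,disease,drug,association,tier,references
KRAS,wild_type,,colorectal cancer,cetuximab,response,approved,PMID:999
TSC1,any_inactivating,,breast cancer,everolimus,response,early_trial,PMID:998
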