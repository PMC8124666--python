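pathway	clone1	clone2	clone3
rRNA_processing_nucleolus_cytosol	1	1	0
O_glycosylation_TSR_domain_proteins	0	0	1
defective_B3GALTL_PpS	0	0	1
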