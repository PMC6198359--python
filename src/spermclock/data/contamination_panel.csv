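locus,chrom,start,stop,sperm_state,somatic_state
DLK1,chr14,101192042,101201539,low,high
SYN_PANEL_1,chr2,20000001,20001000,low,high
SYN_PANEL_2,chr20,5000001,5001000,low,high
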