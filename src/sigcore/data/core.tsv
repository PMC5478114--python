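gene	direction	pathway
Chaf1b	+1	Cell Cycle
Scrn1	+1	Immune Response
CD74	-1	Immune Response
Ccr2	-1	Immune Response
Npy	+1	Cell Migration
Nrp1	-1	Cell Migration
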