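gene	direction	pathway
Aurkb	+1	Cell Cycle
Ccna2	+1	Cell Cycle
Chaf1b	+1	Cell Cycle
Ccnb1	+1	Cell Cycle
Scrn1	+1	Immune Response
C1qb	-1	Immune Response
CD74	-1	Immune Response
Ccr2	-1	Immune Response
Itgb2	-1	Immune Response
Vcam1	-1	Immune Response
CD180	-1	Immune Response
CD72	-1	Immune Response
Npy	+1	Cell Migration
Cldn8	+1	Cell Migration
Nrp1	-1	Cell Migration
Atp7b	+1	Homeostasis
St8sia4	-1	Glycan Metabolism
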