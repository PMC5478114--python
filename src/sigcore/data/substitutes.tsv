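gene	substitute	substitute_pathway	same_pathway	role
Npy	Spink5	Cell Migration	1	ffpe_backup
Ccr2	Ctss	Immune Response	1	ffpe_backup
CD180	Aim2	Immune Response	1	ffpe_backup
CD72	CD48	Immune Response	1	ffpe_backup
Chaf1b	Kif11	Cell Cycle	1	same_pathway
Nrp1	Klrd1	Cell Migration	1	same_pathway
Cldn8	Itga8	Cell Migration	1	same_pathway
Cldn8	Clu	Cell Death	0	top_correlate
St8sia4	Ncf4	Immune Response	0	top_correlate
Ccr2	Rnase6	RNA Catabolic Process	0	top_correlate
Scrn1	Mphosph6	Unassigned	0	top_correlate
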