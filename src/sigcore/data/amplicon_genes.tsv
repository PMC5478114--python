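gene
ERBB2
STARD3
PERLD1
GRB7
C17orf37
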