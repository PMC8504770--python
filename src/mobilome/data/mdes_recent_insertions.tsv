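superfamily	n_sites
Ty3/gypsy	4
hAT	15
Tc1/mariner	8
Mutator	1
MITE	58
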