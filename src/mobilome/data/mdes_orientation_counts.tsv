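category	sense	antisense
next_to_gene	620	573
te_inside_gene	1849	1847
gene_inside_te	205	165
five_prime_region	304	239
three_prime_region	412	406
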