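# Signature-verified TLP gene-family sizes in four small-grain cereal genomes.
species	n_tlp_genes
Hordeum vulgare	19
Brachypodium distachyon	28
Sorghum bicolor	35
Oryza sativa	37
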