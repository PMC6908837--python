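mag_id	completeness	contamination	taxonomy	genome_size_mbp	n_genes
MAG43	21	3.6	Unclassified	0.7	692
MAG44	42	1.8	Pseudomonas	5.5	5207
MAG45	54	0.3	Oxalobacteraceae	2.9	2853
MAG46	29	0	Arthrobacter	2.3	2252
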