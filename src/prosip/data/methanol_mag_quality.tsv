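mag_id	completeness	contamination	taxonomy	genome_size_mbp	n_genes
MAG47	43	4	Actinomycetales	3.4	3359
MAG48	37	0	Rhizobiales	2.3	2418
MAG49	17	2	Alphaproteobacteria	1.4	1477
MAG50	48	5	Proteobacteria	3.1	2996
MAG51	8	0	Proteobacteria	0.3	300
MAG52	23	3	Unclassified	1.4	1374
MAG53	66	4	Rhizobiales	2.3	2354
MAG54	31	3	Bradyrhizobiaceae	1.8	1781
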