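protein_id	protein_name	mag_id	d3_r1	d3_r2	d3_r3	d8_r1	d8_r2	d8_r3
scaff_0000000132_40	Threonine-tRNA ligase	MAG47	97	98	98	98	97	98
scaff_0000127167_4	XoxF-type methanol dehydrogenase	MAG48	55	55	59	72	68	59
scaff_0000032941_13	XoxF-type methanol dehydrogenase	MAG49	95	98	94	-	-	96
scaff_0000001175_15	SOS ribosomal protein L5	MAG50	93	-	93	-	-	-
scaff_0000138535_1	XoxF-type methanol dehydrogenase	MAG51	-	-	-	96	95	95
scaff_0000073426_7	Transaldolase	MAG52	-	-	-	95	-	94
scaff_0000002428_1	Protein with unknown function	MAG53	-	-	-	84	-	84
scaff_0000012663_3	Malate dehydrogenase	MAG54	-	-	-	-	58	67
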