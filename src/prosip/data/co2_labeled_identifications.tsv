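protein_id	protein_name	plant_host	timepoint	atom_percent	mag_id
scaff_0000095019_7	Glyceraldehyde-3-phosphate dehydrogenase	Z. mays	T1	24	MAG43
scaff_0000095019_7	Glyceraldehyde-3-phosphate dehydrogenase	Z. mays	T2	15	MAG43
scaff_0000095019_7	Glyceraldehyde-3-phosphate dehydrogenase	T. aestivum	T2	30	MAG43
scaff_0000016092_2	Cold shock protein CapA	Z. mays	T1	18	MAG44
scaff_0000160764_4	Chaperone DnaK	Z. mays	T1	16	MAG44
scaff_0000030713_6	Protein with unknown function	Z. mays	T2	18	MAG45
scaff_0000049197_5	Colicin I receptor	Z. mays	T2	17	MAG45
scaff_0000017170_6	Enolase	T. aestivum	T2	20	MAG46
scaff_0000017170_6	Enolase	T. aestivum	T2	28	MAG46
scaff_0000125141_2	Dihydrolipoyl dehydrogenase	T. aestivum	T1	16	MAG46
scaff_0000125141_2	Dihydrolipoyl dehydrogenase	T. aestivum	T2	26	MAG46
scaff_0000125141_2	Dihydrolipoyl dehydrogenase	T. aestivum	T2	46	MAG46
scaff_0000159039_6	Protein with unknown function	T. aestivum	T2	34	MAG46
scaff_0000063839_3	Chaperonin GroEL	Z. mays	T1	29	MAG46
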