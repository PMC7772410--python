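locus_tags	assigned_function	ec_number	gene_symbol	section_label
0080| 0744| 0939| 1172| 1932	AAA+ ATPase		atad3A	Cell division
0647	Cell division inhibitor		sepF	Cell division
1346	Cell division control protein		minE	Cell division
1419	DNA replication protein 6-2		cdc6-2	Cell division
1654	Structural maintenance of chromosomes protein 1		smc1	Cell division
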