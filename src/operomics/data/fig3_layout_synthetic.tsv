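locus_tag	start	end	strand	is_hp	label
mru_0101	1000	1899	+	1	hsp
mru_0102	2000	2899	+	1	hsp
mru_0103	3000	3899	+	1	hsp
mru_0104	4000	4899	+	1	chaperone
mru_0105	5000	5899	+	1	hsp
mru_f001	8000	8899	+	0	known function gene
mru_0201	12000	12899	-	1	TRAM
mru_0202	13000	13899	-	1	TRAM
mru_0203	14000	14899	-	1	rna chaperone
mru_0204	15000	15899	-	1	TRAM
mru_0301	22000	22899	+	1	dsr
mru_0302	23000	23899	+	1	dsr
mru_0303	24000	24899	+	1	sulfite reductase subunit
mru_0304	25000	25899	+	1	dsr
mru_0305	26000	26899	+	1	dsr
mru_f002	30000	30899	-	0	known function gene
mru_0401	33000	33899	+	1	cbs
mru_0402	34000	34899	+	1	cbs
mru_0403	35000	35899	+	1	cbs
mru_0404	36000	36899	+	1	adenosyl binding protein
mru_0501	43000	43899	-	1	anti-toxin
mru_0502	44000	44899	-	1	toxin
mru_0503	45000	45899	-	1	anti-toxin
mru_0504	46000	46899	-	1	anti-toxin
mru_0505	47000	47899	-	1	toxin
mru_0506	48000	48899	-	1	anti-toxin
mru_f003	51000	51899	+	0	known function gene
mru_0601	55000	55899	+	1	cas
mru_0602	56000	56899	+	1	cas
mru_0603	57000	57899	+	1	cas
mru_0604	58000	58899	+	1	crispr repeat protein
mru_0605	59000	59899	+	1	cas
mru_0606	60000	60899	+	1	cas
mru_0607	61000	61899	+	1	crispr repeat protein
mru_0608	62000	62899	+	1	cas
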