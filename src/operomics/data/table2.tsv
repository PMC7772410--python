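locus_tags	assigned_function	ec_number	gene_symbol	section_label
0757	Bro N-terminal domain protein		dxs	Transcriptional regulation
0349	Nitrogen repressor		nrpR	Transcriptional regulation
1052	Heat-inducible transcriptional repressor		hrcA	Transcriptional regulation
1099	Translation initiation factor 3		tif3	Transcriptional regulation
1366| 2156	Arsenical resistance operon repressor		arsR	Transcriptional regulation
1862	Copper-sensing transcriptional repressor		csoR	Transcriptional regulation
0488| 0490| 0499| 0658| 0764| 0780| 0790| 0801| 0930| 1131| 1147| 1150| 1364| 1590| 1796	Transcription factor		tf2B	Transcriptional regulation
1185	Cold shock protein			Transcriptional regulation
1108	DEAD/DEAH box helicase		polB	Transcriptional regulation
0877	Preprotein translocase		secY	Transcriptional regulation
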