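key	value
hp_count	756
coding_genes	2278
printed_hp_percent	73
annotated_count	257
annotated_percent	34
metabolic_enzymes_abstract	96
metabolic_subsystems_abstract	17
metabolic_enzymes_conclusion	119
metabolic_subsystems_conclusion	18
transcriptional_regulators_abstract	31
transcriptional_regulators_text	26
transcriptional_regulators_table_distinct	25
transport_proteins_abstract	23
binding_proteins_abstract	11
tm_proteins_text	91
operon_like_clusters	6
operon_cluster_genes	32
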