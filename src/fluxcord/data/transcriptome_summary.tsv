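# Published dataset-level bookkeeping counts for the two-accession
# embryo transcriptome.
statistic	value
n_transcripts_annotated	89315
n_gene_identifiers	19087
n_transcript_T_calls	2165
n_transcript_S_calls	1958
n_gene_T_calls	1064
n_gene_T_sum_agrees	847
n_gene_S_calls	911
n_gene_S_sum_agrees	717
n_model_genes_found	860
n_reaction_T_calls	45
n_reaction_T_flux_matches	23
n_reaction_S_calls	82
n_reaction_S_flux_matches	4
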