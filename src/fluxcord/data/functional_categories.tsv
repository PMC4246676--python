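# Published per-category counts of gene-level S and T calls (MapMan
# BIN codes); n_S / n_T are the printed counts, from which the T/S
# ratio is recomputed.
bin_code	n_S	n_T	classification
35	197	232	Not assigned, no ontology/unknown
29	114	142	Protein
27	77	91	RNA
26	31	37	Misc
34	30	37	Transport
20	31	35	Stress
30	27	37	Signaling
31	30	25	Cell
28	31	19	DNA
1	9	29	PS, lightreaction/photorespiration/calvin cycle
33	16	22	Development
11	15	18	Lipid metabolism
13	13	19	Amino acid metabolism
10	22	7	Cell wall
16	10	19	Secondary metabolism
17	12	10	Hormone metabolism
23	9	9	Nucleotide metabolism
9	1	15	Mitochondrial electron transport / ATP synthesis
3	7	7	Minor CHO metabolism
21	4	10	Redox, thioredoxin/ascorbate/glutaredoxins
8	5	7	TCA / org transformation
4	4	5	Glycolysis
2	4	1	Major CHO metabolism, synthesis.starch/degradation.starch
18	3	2	Co-factor and vitamine metabolism
19	3	2	Tetrapyrrole synthesis
7	3	1	OPP, oxidative PP
5	1	2	Fermentation
12	2	1	N-metabolism
15	1	2	Metal handling
14	1	1	S-assimilation
24	1	1	Biodegradation of Xenobiotics
32	0	2	Micro RNA, natural antisense etc
6	1	0	Gluconeogenesis / glyoxylate cycle
22	1	0	Polyamine metabolism
25	1	0	C1-metabolism
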