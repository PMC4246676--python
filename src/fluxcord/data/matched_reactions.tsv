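# Published worked example: 27 reactions whose change in gene expression
# correlates with the difference in flux between the two accessions.
# responsiveness = lower;upper flux-bound call; call_string = per-gene
# transcript-level significance calls ("(X)" = no transcripts found).
index	abbreviation	name	responsiveness	call_string
26	PFK_c	phosphofructokinase	N;S	(S)()()()()
55	RPI_p	ribose-5-phosphate isomerase	T;T	(T)()
93	PiC_c_m	phosphate carrier	T;T	()()(T)
95	H_PYR_sym_c_p	pyruvate transport	T;T	(T)
252	ADEK_c	adenosine kinase	T;T	()(T)
255	SHMT_c	glycine hydroxymethyltransferase	T;T	()()(X)()()(TT)
284	ABUTsynth_p	acetolactate synthase	T;T	(T)()()
294	IPMDY_p	3-isopropylmalate dehydratase	T;T	(TT)()(X)(T)
295	IPMD_p	3-isopropylmalate dehydrogenase	T;T	(X)(T)()
312	ACLACsynth_p	acetolactate synthase	T;T	(T)()()
318	ASUCS_p	adenylosuccinate synthase	T;T	(T)
320	IMPsynth_p	IMP cyclohydrolase	T;T	(T)
333	Phesynth_p	arogenate dehydratase	T;T	()()()()(X)(TT)
335	HOM_p	homoserine dehydrogenase	T;T	()(TT)
337	AK_p	aspartate kinase	T;T	()()(TT)()()
340	DHS_p	3-deoxy-7-phosphoheptulonate synthase	T;T	(TT)()()
344	starchsynth_p	starch synthase	S;S	()()(S)(SSS)(SS)()()()()
348	PURH_p	phosphoribosylaminoimidazolecarboxamide formyltransferase	T;T	(T)
355	Glysynth_p	glycine hydroxymethyltransferase	T;T	()()(X)()(T)()(TT)
357	IGLPS_p	indole-3-glycerol-phosphate synthase	T;T	()(T)
361	Thrsynth_p	threonine synthase	T;T	()(TT)
456	SUCLA_m	Succinate-CoA ligase (ADP-forming)	T;T	()(T)()
458	GDC2_m	aminomethyltransferase	S;S	(S)
499	ACCase_c	acetyl-CoA carboxylase	T;T	(T)
541	PDHa_m	dihydrolipoyllysine-residue acetyltransferase	S;S	(S)(S)()
576	CMK_p	4-diphosphocytidyl-2-C-methyl-D-erythritol kinase 1	T;T	(T)
621	DHCRed_c	7-dehydrocholesterol reductase	T;T	(TTTT)
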