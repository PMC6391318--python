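rs_id	group	n	ref_allele	alt_allele	n_hom_ref	n_het	n_hom_alt	hwe_p_printed	ref_count_printed	ref_freq_printed	alt_count_printed	alt_freq_printed	allele_p_printed
rs16999141	MJD	109	T	C	57	52	0	0.005	166	0.76	52	0.24	<0.001
rs16999141	control	49	T	C	12	29	8	0.407	53	0.54	45	0.46	.
rs56268847	MJD	109	A	G	46	60	3	0.007	152	0.70	66	0.30	<0.001
rs56268847	control	49	A	G	43	5	1	0.271	91	0.93	7	0.07	.
rs10467857	MJD	109	G	C	56	53	0	0.004	165	0.76	53	0.24	<0.001
rs10467857	control	49	G	C	13	26	10	0.901	52	0.53	46	0.47	.
rs77086230	MJD	109	C	T	103	6	0	0.957	212	0.97	6	0.03	<0.001
rs77086230	control	49	C	T	44	5	0	0.932	93	0.95	5	0.05	.
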