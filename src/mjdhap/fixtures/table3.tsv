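haplotype	freq_control	freq_mjd	delta_printed	p_printed
T-T-A-C-A-C	0.283	0.482	0.278	<0.001
T-T-A-C-C-A	0.013	0	.	.
T-T-A-G-A-C	0.119	0.382	0.298	<0.001
T-T-A-G-C-C	0.000	0.045	0.045	.
T-T-A-G-C-A	0.003	0	.	.
T-T-G-G-A-C	0.013	0.009	0.003	<0.001
T-T-G-G-C-A	0.013	0	.	.
T-T-G-C-A-C	0.006	0.018	0.012	<0.001
T-C-G-G-C-A	0.019	0	.	.
G-C-G-G-C-A	0.321	0	.	.
G-C-G-G-A-C	0.006	0	.	.
G-C-G-C-C-A	0.035	0	.	.
G-C-G-C-A-C	0.013	0	.	.
G-C-A-G-C-A	0.028	0	.	.
G-C-A-G-A-C	0.009	0.009	0	<0.001
G-T-A-G-A-C	0.016	0.055	0.040	<0.001
G-T-A-G-C-A	0.003	0	.	.
G-T-A-C-A-C	0.009	0	.	.
G-T-A-C-C-A	0.009	0	.	.
G-T-G-G-A-C	0.003	0	.	.
G-T-G-G-C-A	0.066	0	.	.
G-T-G-C-C-A	0.013	0	.	.
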