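marker_id	rs_id	kind	offset_kb	domain
TAT_223	.	STR	-223	1+
GT_199	.	STR	-199	1+
ATA_194	.	STR	-194	1+
AC_21	.	STR	-21	1+
rs12590497	rs12590497	SNP	-3.60	G,T
rs16999141	rs16999141	SNP	-3.30	T,C
rs10146519	rs10146519	SNP	-2.95	T,G
rs1048755	rs1048755	SNP	-2.60	A,G
rs12586535	rs12586535	SNP	-0.851	C,T
rs12586471	rs12586471	SNP	-0.727	T,C
rs56268847	rs56268847	SNP	-0.490	A,G
rs10467858	rs10467858	SNP	-0.107	G,A
rs10467857	rs10467857	SNP	-0.065	C,G
rs10467856	rs10467856	SNP	-0.054	T,C
rs12895357	rs12895357	SNP	0.012	C,G
rs7158733	rs7158733	SNP	0.143	A,C
rs3092822	rs3092822	SNP	0.203	C,A
rs77086230	rs77086230	SNP	0.320	C,T
rs79316375	rs79316375	SNP	0.410	C,T
rs8004149	rs8004149	SNP	2.763	G,A
rs111735934	rs111735934	SNP	2.795	G,A
rs181752420	rs181752420	SNP	2.899	C,T
rs7142326	rs7142326	SNP	2.937	A,G
rs74071847	rs74071847	SNP	3.005	C,T
AAAC	.	STR	4.5	1+
GT	.	STR	5.0	1+
AC_190	.	STR	190	1+
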