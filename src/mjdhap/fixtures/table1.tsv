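rs_id	joseph	A	B	C	D	E	F	G	H	I	J	K	L	M
n_families	.	10	12	1	8	1	1	11	1	1	1	2	1	1
rs12590497	T	T	T	T	T	T	T	T	T	T	G	G	G	T
rs16999141	T	T	T	T	T	T	T	T	T	T	T	T	C	T
rs10146519	G	G	G	G	G	G	G	G	G	G	G	G	G	G
rs1048755	A	A	A	A	A	A	A	A	G	A	A	A	A	G
rs12586535	T	T	T	T	T	T	C	T	T	T	T	T	T	T
rs12586471	C	C	C	C	C	C	T	C	C	C	C	C	C	C
rs56268847	A	A	G	G	A	A	A	G	G	G	G	A	A	G
rs10467858	A	A	A	A	A	A	A	A	A	A	A	A	A	G
rs10467857	G	G	G	G	G	C	G	G	G	G	G	G	G	G
rs10467856	C	C	C	C	C	C	C	C	C	C	C	C	C	C
rs12895357	C	C	C	C	G	G	G	G	G	G	G	G	G	C
rs7158733	A	A	A	A	A	A	A	A	A	C	A	A	A	A
rs3092822	C	C	C	C	C	C	C	C	C	C	C	C	C	C
rs77086230	C	C	C	T	C	C	C	C	C	C	C	C	C	C
rs79316375	C	C	C	C	C	C	C	C	C	C	C	C	C	C
rs8004149	A	A	A	A	A	A	A	A	A	A	A	A	A	A
rs111735934	G	G	G	G	G	G	G	G	G	G	G	G	G	G
rs181752420	C	C	C	C	C	C	C	C	C	C	C	C	C	C
rs7142326	G	G	G	G	G	G	G	G	G	G	G	G	G	G
rs74071847	C	C	C	C	C	C	C	C	C	C	C	C	C	C
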