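lineage	row_id	family	TAT_223	GT_199	ATA_194	AC_21	AAAC	GT	AC_190	AAAC_note	age_mean_printed	age_pm_printed
A	A01	Fam 10	10	20	10	13	7	16	15	.	16335	1966
A	A02	Fam 44	10	20	10	13	7	16	15	.	16335	1966
A	A03	Fam 34	11	20	10	13	7	15	15	.	16335	1966
A	A04	Fam 1	10	20	10	13	7	20	18	.	16335	1966
A	A05	Fam 8	10	22	10	13	7	16	15	.	16335	1966
A	A06	Fam 5	10	26	10	13	7	16	15	.	16335	1966
A	A07	Fam 11	10	24	10	12	7	14	18	.	16335	1966
A	A08	Fam 24	14	22	10	12	8	20	15	.	16335	1966
A	A09	Fam 29	16	22	10	13	7	20	15	.	16335	1966
A	A10	Fam 47	16	24	10	14	5	20	16	.	16335	1966
B	B01	Fam 41	10	22	10	12	7	20	16	.	9272	1352
B	B02	Fam 23	10	22	10	13	7	20	16	.	9272	1352
B	B03	Fam 16	10	21	11	13	7	20	16	.	9272	1352
B	B04	Fam 4	11	24	10	12	7	20	15	.	9272	1352
B	B05	Fam 49	10	22	10	12	7	16	16	.	9272	1352
B	B06	Fam 25	10	22	10	14	7	16	16	.	9272	1352
B	B07	Fam 40	10	22	9	12	7	17	19	.	9272	1352
B	B08	Fam 30	10	22	9	12	7	20	16	.	9272	1352
B	B09	Fam 37	10	22	9	12	8	20	16	.	9272	1352
B	B10	Fam 45	10	20	9	12	7	20	16	.	9272	1352
B	B11	Fam 35	15	22	8	12	7	20	16	.	9272	1352
B	B12	Fam 48	16	22	9	12	6	20	15	.	9272	1352
D	D01	Fam 1	10	20	10	13	7	16	15	.	11837	1871
D	D02	Fam 7	10	20	10	13	7	16	15	.	11837	1871
D	D03	Fam 38	10	20	10	13	7	16	15	.	11837	1871
D	D04	Fam 50	11	19	12	13	7	15	15	.	11837	1871
D	D05	Fam 19	13	22	9	13	7	16	15	.	11837	1871
D	D06	Fam 3	16	23	10	13	7	16	15	.	11837	1871
D	D07	Fam 9	17	21	10	13	7	17	15	.	11837	1871
D	D08	Fam 26	16	21	10	13	7	20	15	.	11837	1871
G	G01	Fam 13	10	22	9	12	7	20	16	.	9254	1411
G	G02	Fam 43	10	22	8	12	7	20	16	.	9254	1411
G	G03	Fam 22	10	22	9	12	7	20	15	.	9254	1411
G	G04	Fam 33	10	22	9	15	7	19	16	5	9254	1411
G	G05	Fam 17	10	22	9	14	8	16	16	.	9254	1411
G	G06	Fam 6	12	22	10	12	7	20	16	.	9254	1411
G	G07	Fam 32	16	22	9	12	7	20	16	.	9254	1411
G	G08	Fam 46	16	21	10	12	7	20	15	.	9254	1411
G	G09	Fam 27	10	22	9	12	5	20	16	.	9254	1411
G	G10	Fam 36	10	22	10	12	5	20	15	.	9254	1411
G	G11	Fam 42	11	22	11	12	5	20	20	.	9254	1411
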