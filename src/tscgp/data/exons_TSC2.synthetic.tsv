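# SYNTHETIC exon boundary table for TSC2 (NM_000548.3 coding geometry).
# Exons are numbered 1-41 over coding exons (LOVD-style numbering); the single
# non-coding guiding exon is listed as exon 0 with an empty span.
# These boundaries are constructed, not transcript-accurate: they satisfy the published
# domain/exon attributions (LZD exon 3 / aa 81-98; CCD1 exon 10 / aa 346-371; CCD2
# exon 26 / aa 1008-1021; TAD1 exons 29-30 / aa 1163-1259 with exon 29 = 3433-3611;
# GAPD exons 34-38 / aa 1517-1674; TAD2 exons 39-40 / aa 1690-1744; CaBD exons
# 40-41 / aa 1740-1755) and the true CDS length 5424. Replace with an LOVD/RefSeq
# derived table (same columns, named exons_TSC2.tsv) for coordinate-accurate work.
exon	cds_start	cds_end	coding
0			0
1	1	150	1
2	151	240	1
3	241	330	1
4	331	450	1
5	451	570	1
6	571	690	1
7	691	810	1
8	811	930	1
9	931	1035	1
10	1036	1120	1
11	1121	1250	1
12	1251	1380	1
13	1381	1510	1
14	1511	1640	1
15	1641	1770	1
16	1771	1900	1
17	1901	2030	1
18	2031	2160	1
19	2161	2290	1
20	2291	2420	1
21	2421	2550	1
22	2551	2680	1
23	2681	2810	1
24	2811	2940	1
25	2941	3021	1
26	3022	3132	1
27	3133	3282	1
28	3283	3432	1
29	3433	3611	1
30	3612	3780	1
31	3781	4030	1
32	4031	4290	1
33	4291	4548	1
34	4549	4650	1
35	4651	4760	1
36	4761	4870	1
37	4871	4960	1
38	4961	5030	1
39	5031	5068	1
40	5069	5238	1
41	5239	5424	1
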