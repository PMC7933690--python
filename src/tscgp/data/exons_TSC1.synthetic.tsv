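# SYNTHETIC exon boundary table for TSC1 (NM_000368.4 coding geometry).
# CDS coordinates are 1-based inclusive. Exons 1-2 are non-coding (empty CDS span).
# These boundaries are constructed, not transcript-accurate: they satisfy the published
# domain/exon attributions (TMD in exon 6 covering aa 127-144; TID exons 8-11; CCD
# exons 18-22 covering aa 730-996; exon 8 ending at c.737) and the true CDS length 3495.
# Replace this file with an LOVD/RefSeq-derived table (same columns, named
# exons_TSC1.tsv) for coordinate-accurate annotation.
exon	cds_start	cds_end	coding
1			0
2			0
3	1	140	1
4	141	260	1
5	261	378	1
6	379	480	1
7	481	600	1
8	601	737	1
9	738	860	1
10	861	990	1
11	991	1120	1
12	1121	1250	1
13	1251	1440	1
14	1441	1600	1
15	1601	1760	1
16	1761	1920	1
17	1921	2187	1
18	2188	2340	1
19	2341	2520	1
20	2521	2700	1
21	2701	2850	1
22	2851	2990	1
23	2991	3495	1
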