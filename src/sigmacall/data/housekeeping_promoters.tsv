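#sigmacall	schema=housekeeping	version=1
rank	m35_model	m35_start	m35_seq	m10_start	m10_seq	locus_tag	gene	published_score
2376	1	-34	TTGACAAGGA	-13	TCTATAGTTG	Rmet_R0003	rplY	13.6
2	1	-35	TTGCAACGGC	-15	TGTATAATTC	Rmet_6415	rplM	12.6
53	1	-34	TTGATTGATA	-13	GCTAATATCG	Rmet_0722	rpsA	10.6
18	2	-36	TTTGTTTGGG	-14	GCTATACTCT	Rmet_0749	rimM	10.9
1211	1	-37	TTGCCGGTCC	-15	CTTAACATCG	Rmet_0920	rpsO	11.4
886	1	-36	TTGCACGCGA	-14	GTTATACTTG	Rmet_R0015	thrS	12.4
714	1	-37	TTGCGTAACG	-16	TATAAAATTC	Rmet_1161	infC	10.8
2673	1	-36	TTGATAACGA	-13	GTCAAATTCA	Rmet_1162	rpmI	11.4
68	2	-35	TTGCGTTCCG	-14	AAGATACTGG	Rmet_1166	ihfA	10.6
245	2	-39	TTTGTTTGCG	-15	GCTATAATTG	Rmet_1975	dnaB	6.9
49	1	-35	TTGCGGGAAG	-13	GCTATACTCG	Rmet_1979	rpsF	12.2
1413	1	-36	TGGAAAGCCT	-15	GTTACAATGC	Rmet_2134	trxA	12.3
14	1	-35	TGGCGCACCG	-15	GCTATGATGC	Rmet_2135	rho	9.1
31	1	-35	TTGCACCTGC	-13	GCCATAATCC	Rmet_2137	rpmE	12.2
7	1	-35	TTGATTCGTC	-13	TCTATAATGT	Rmet_2870	rpmB	14.2
38	1	-36	TTGCCTGTCC	-14	TGTATAATCG	Rmet_2904	rpsT	14.4
33	1	-35	TTGCAGTTTT	-14	TTTATAATCA	Rmet_3106	rplU	12.6
1622	1	-39	TGGCGCCGTG	-15	GATAAAGTGG	Rmet_3291	rpoA	4.9
60	1	-34	TTGCAAGTCC	-14	GCTATAATCC	Rmet_3307	rplN	11.6
526	1	-34	TTGCCCTTTC	-13	GTTATAGTGT	Rmet_3317	rplC	11.6
219	1	-34	TTGACCATTG	-13	GCTAGAGTGC	Rmet_3327	rpsL	11.6
2084	1	-37	TTCAGTTCCG	-14	GGTATCATCC	Rmet_3336	rplJ	9.9
11	1	-35	TTGACAGCCA	-14	ACCATAATCA	Rmet_R0059	tRNA	14.6
2648	1	-36	TGGAAGTGGT	-13	TCTAAGCTTC	Rmet_R0060	tRNA	8.9
2789	1	-36	TTGACGGGGA	-13	TGGATGATGT	Rmet_R0063	tRNA	12.4
2182	1	-35	TTGTTGGGGA	-14	AGTAACGTAG	Rmet_R0053	tRNA	9.6
1312	1	-35	TTGAACTGAA	-11	CTCAGATTGA	Rmet_R0063	tRNA	9.2
235	1	-34	TTGACGAAAC	-13	TGCATAATCT	Rmet_R0064	tRNA	12.6
19	1	-35	TTGACTGATG	-13	AATAGAATCG	Rmet_3501	atpI	14.2
1108	1	-39	TGGCGCGGCT	-13	GATACGCTGG	Rmet_3501	atpI	1.9
15	1	-35	TTGTTCAGGT	-14	CATATAATGC	Rmet_0260	coxB	12.6
2505	2	-33	TTTCTCCCCC	-13	GTGAAATTGG	Rmet_0927	nuoA	5.1
1708	1	-33	TTCATTGTTC	-13	GTGATGCTGA	Rmet_2039	cco	6.1
389	1	-36	TTGCCCTGAA	-14	GGCACTATCA	Rmet_2188	ftsH	11.4
2159	1	-34	TTGTTATCTC	-14	CCCAACTTGT	Rmet_2188	ftsH	7.6
1336	1	-34	TTGCAAAGAC	-12	CGTACAATGC	Rmet_2621	zupT	12.2
2410	1	-34	TTGTCAGGGG	-13	AGCACACTGG	Rmet_2623	ndh	10.6
577	2	-36	TTGCTTTTCG	-14	GACAGAATGT	Rmet_3227	sspA	11.4
317	2	-37	TATCGTCGCC	-15	GGTATAATTT	Rmet_3230	petA	9.4
1092	1	-36	TTCCCACGAT	-13	GGCATGATCA	Rmet_3230	petA	10.9
977	2	-39	TATCGGCGCG	-14	GTTATCCTGC	Rmet_2031	infB	2.4
391	1	-35	TTGATACCGG	-13	CCTACACTAC	Rmet_2192	greA	13.2
861	1	-36	TTGACATCAA	-15	CCTACACTCG	Rmet_2489	mdh	13.8
165	2	-38	TATTGGTGCG	-13	GCTAAAATCA	Rmet_2486	sdhC	4.4
2042	1	-33	TGGCGTGCCC	-13	TGCATAATAT	Rmet_2895	icd	7.1
2941	1	-38	TTGCACCTCC	-14	GGCAAAATTC	Rmet_3729	icdA	7.4
1295	1	-36	TTGCATCGAT	-15	TCTAGTATAT	Rmet_4268	citA	10.8
723	1	-35	TTGATCTGGC	-14	TCTACAATCA	Rmet_5296	acnB	12.6
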