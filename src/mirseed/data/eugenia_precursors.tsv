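name	contig	group	length	gc_percent	mfe	amfe	mfei	seq_5p	count_5p	seq_3p	count_3p	total_reads
eun-MIR156	Contig92889	conserved	97	54.64	-55.20	-56.91	-1.04	TTGACAGAAGATAGAGAGCAC	83933	GCTCTCCCTCTCCTGTCAACA	1	85396
eun-MIR159	Contig93245	conserved	163	45.40	-55.86	-34.27	-0.75	AGCTGCTGGTCTATGGATCCC	376	CTTGCATATGCCAGGAGCTTC	493	1302
eun-MIR160	Contig81816	conserved	116	53.45	-54.30	-46.81	-0.88	TGCCTGGCTCCCTGTATGCCA	293	GCGTATGAGGAGCCAAGCATA	22	323
eun-MIR162	Contig165400	conserved	108	48.15	-35.80	-33.15	-0.69	GGAGGCAGCGGTTCATCGATC	24	TCGATAAACCTCTGCATCCAG	10713	10884
eun-MIR166	Contig94223	conserved	228	43.42	-72.40	-31.75	-0.73	GGAATGTTGTCTGGCTCGAGG	11016	TCGGACCAGGCTTCATTCCCC	381733	409546
eun-MIR167-1	Contig126350	conserved	90	45.56	-50.00	-55.56	-1.22	TGAAGCTGCCAGCATGATCTGA	616862	AGATCATCTGGCAGTTTCAAC	262	620306
eun-MIR167-2	Contig163487	conserved	615	37.40	-163.60	-26.60	-0.71	TGAAGCTGCCAGCATGATCTGG	32188	TCAGGTCATCTTGCAGCTTCA	939	34461
eun-MIR167-3	Contig784s	conserved	81	48.15	-38.60	-47.65	-0.99	TGAAGCTGCCAGCGTGATCTCA	16305	ATCAGATCATGTGGCAGCTTCACC	73	22056
eun-MIR167-4	Contig784a	conserved	81	48.15	-38.70	-47.78	-0.99	TGAAGCTGCCACATGATCTGA	71	ND	-	72
eun-MIR169	Contig142088	conserved	730	39.18	-160.80	-22.03	-0.56	TTATAGGCGATTGGAGGTATG	876	TTAGCTAAAGTCGTCTTGCCCA	6818	8961
eun-MIR172-1	Contig83802	conserved	122	47.54	-55.10	-45.16	-0.95	CAGGTGTAGCATCATCAAGAT	36	AGAATCTTGATGATGCTGCAT	495	1076
eun-MIR172-2	Contig113567	conserved	92	42.39	-39.70	-43.15	-1.02	GCAGCATCATCAAGATTCACA	12	AGAATCTTGATGATGCTGCAT	495	523
eun-MIR172-3	Contig85928	conserved	165	43.64	-71.20	-43.15	-0.99	GTAGCATCATCAAGATTCACA	33	AGAATCTTGATGATGCTGCAT	495	1048
eun-MIR395	Contig114717	conserved	88	51.14	-47.50	-53.98	-1.06	TCCCCTAGAGTTCTCCTGAACA	107	ATGAAGTGTTTGGGGGAACTC	1356	1659
eun-MIR396-1	Contig94388	conserved	160	42.50	-68.60	-42.88	-1.01	TTCCACGGCTTTCTTGAACTG	217485	GTTCAATAAAGCTGTGGGAAG	2028	223828
eun-MIR396-2	Contig153308	conserved	128	42.19	-49.10	-38.36	-0.91	TTCCACAGCTTTCTTGAACTG	23061	GTTCAAGCTAGCTGTGGGAAG	12981	64439
eun-MIR397-1	Contig87345s	conserved	126	51.59	-68.80	-54.60	-1.06	TCATTGAGTGCAGCGTTGAT	626	CGGTTTCGACAGCGCTGCACT	59	1052
eun-MIR397-2	Contig87345a	conserved	126	51.59	-63.20	-50.16	-0.97	TGCAGCGCTGTCGAAACCGAT	20	TCAACGCTGCACTCAATGATG	273	322
eun-MIR482-1	Contig88445	conserved	153	53.90	-94.60	-61.43	-1.14	CATGGGTTGTTTGGTGAGAGG	24202	TCTTGCCAATACCACCCATGCC	70833	100235
eun-MIR482-2	Contig88445	conserved	139	53.96	-71.00	-51.08	-0.95	GAAATGGGAGGGTGGGAAAGA	982	TTTCCTATTCCTCCCATTCCAT	3371	5574
eun-MIR482-3	Contig85065	conserved	169	50.89	-92.40	-54.67	-1.07	GAGATTCGAGCTACCGGAAGTTGTG	329	TTCCCAAGGCCGCCCATTCCGA	14915	17039
eun-MIR530	Contig18750	conserved	183	51.37	-82.30	-44.97	-0.88	TCTGCATTTGCACCTGCACCT	185	AGGTGCGGGTGCAGGTGCAGA	12	280
eun-MIR535-1	Contig68094	conserved	102	50.00	-42.60	-41.76	-0.84	TGACAACGAGAGAGAGCACGC	62562	GTGCTCTCTATCGCTGTCATA	4199	76334
eun-MIR535-2	Contig71803	conserved	100	49.00	-47.00	-47.00	-0.96	TGACAACGAGAGAGAGCACGC	62562	TGCTCTCTACCGTTGTCATG	116	72263
eun-MIR827	Contig93928	conserved	81	45.68	-44.30	-54.69	-1.20	CTTTGTTGATGGCCATCTAATC	27	TTAGATGACCATCAGCGAACA	266	304
eun-nMIR001-1	Contig164780s	novel	820	54.39	-451.70	-55.09	-1.01	TCGGCTGTCAATTTCTGGATT	185919	ATCCAGAAATTGGCAGCCGTT	110	192103
eun-nMIR001-2	Contig164780a	novel	820	54.39	-446.00	-54.39	-1.00	CAATTTCTGGATTTCAGTTCG	20	TCGAACTGAAATCCAGAAATT	2	63
eun-nMIR002	Contig29785	novel	173	30.06	-56.70	-32.77	-1.09	CGAAAAATGATTGGTTGTATCGCT	18	CGATCTAATCAATCATTTTTCGGG	2	21
eun-nMIR003	Contig121100	novel	110	48.18	-63.20	-57.45	-1.19	TACTCGTTCCGTTGATCCATC	88	TGGATCAATAGAACGAGCAGGTGA	157	561
eun-nMIR004-1	Contig37387s	novel	104	29.81	-47.10	-45.29	-1.52	TCGTAAATCCACTATATCTCT	3	TAGATATAGTGGATTTTCGAT	9	13
eun-nMIR004-2	Contig37387a	novel	104	29.81	-46.40	-44.62	-1.50	ND	-	CAGAGATATAGTGGATTTACG	314	385
eun-nMIR005	Contig143563	novel	106	34.91	-21.40	-20.19	-0.58	ND	-	GAGAATGATGAGTTAAATGGA	12	30
eun-nMIR006	Contig113617	novel	113	33.63	-42.70	-37.79	-1.12	TCTCTGTTGATCTGATAAATA	19	TTTGTCGGATGAACAGGGAAT	18	55
eun-nMIR007	Contig116664r	novel	96	46.88	-55.80	-58.13	-1.24	TAGGGTCAGATCGCTACTTAG	211	TAAGTGGTGATCTGACTCTAA	4446	5750
eun-nMIR008	Contig79716	novel	426	43.66	-228.00	-53.52	-1.23	TCGAGCCCCTCCCACAGATTG	313	ATCTGTGGAAGAGACTCGACT	8403	13617
eun-nMIR009	Contig81320	novel	1545	37.41	-397.90	-25.75	-0.69	TTCAAGTCTAACAACCTCAGCT	5774	TGGAGGTTGTTTGGCTTGAGCT	1968	11577
eun-nMIR010	Contig84248	novel	350	48.86	-143.30	-40.94	-0.84	TGCTGTTCTTCCGTTCACGAAT	309	TCGTGAAGGAAGAATGTGCAAT	6340	10307
eun-nMIR011	Contig164559	novel	207	51.21	-98.70	-47.68	-0.93	GCTCGAGGTCAGTTTGTCGCC	1553	CGGCAAACTGGACCTCGAGATC	110	2884
eun-nMIR012	Contig167957	novel	164	35.98	-91.80	-55.98	-1.56	CATGTAACAAGTTGGCTGTCA	126	TTCATGGACAGCCAGCTTATT	3	243
eun-nMIR013	Contig87665	novel	179	56.42	-84.90	-47.43	-0.84	TGAAGCAGATCAAGAACCCAG	155	TCTCGTTCCGCTTCATCTGAA	2	172
eun-nMIR014	Contig200629r	novel	87	55.17	-23.40	-26.90	-0.49	ND	-	GCATCACTAGCTTACGCTCTG	30	159
eun-nMIR015	Contig165886	novel	124	37.90	-45.10	-36.37	-0.96	ND	-	CAATGAACGCATTTGCAGGTG	21	22
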