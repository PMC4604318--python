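number	five_prime_id	three_prime_id	family	reference_location	gap_aa	forward_primer	reverse_primer	designed_bp	estimated_bp	validated
1	Unigene91380_All	Unigene105912_All	PHT1	82-170+348-448	178	TAGTTGTGGAGGAGAAATGG	AGGATGGAGAAGGTGACG	558	1092	no
2	Unigene5546_All	Unigene11489_All	PHT1	5'-157+229-319	72	CTTTTGGGGCGTCTGTA	GAACCACGTGCTTGTGG	553	769	no
3	Unigene5546_All	Unigene47851_All	PHT1	5'-157+166-3'	9	CTTTTGGGGCGTCTGTAC	TTCCCTTCGCTTTTTGTG	677	704	no
4	Unigene16022_All	Unigene50223_All	PHT1	5'-91+417-3'	326	ATTTCATCACACACCCAG	ATTTACCCATAGACTCCG	854	1832	no
5	Unigene16022_All	Unigene90558_All	PHT1	5'-91+417-3'	326	ATTTCATCACACACCCAGA	CAAGAGATTTACCCATAGACTC	860	1838	no
6	Unigene11489_All	Unigene63539_All	PHT1	229-319+412-493	93	CAGATAGACGCCGATGAGG	GCAACCAAGAACAATAAGAGAG	416	695	yes
7	Unigene48391_All	Unigene44133_All	PHT1	5'-63+404-3'	341	CTTTCCACCTCAAGTCAT	GTGCAACCAAGAACAATAAGA	587	1610	no
8	Unigene53055_All	Unigene44133_All	PHT1	5'-163+404-3'	241	TCTGTATCTCCCTCCTAAC	CCAAGAACAATAAGAGAGTT	632	1355	yes
9	Unigene125621_All	Unigene61379_All	PHT3	5'-68+131-277	63	CCCCATCTCCACTCCTGTT	AAGGTTGACGGTGGTGTTC	566	755	no
10	Unigene141416_All	Unigene129694_All	PHT3	5'-233+210-281	none	CTGCTATCACCCCTCTTG	CCTTGGTTCAATTTTTATCC	745	745	yes
11	Unigene141415_All	Unigene129694_All	PHT3	8-87+210-281	123	AAAGTATAATGGTAGGAAGTCC	GTTCAATTTTTATCCTCAGG	458	827	no
12	Unigene29837_All	Unigene46396_All	PHT4	5'-230+292-3'	62	GTGTTGCTTTGTGGTCCT	CCCATGTAATATTCCGGT	962	1148	no
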