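number	five_prime_id	three_prime_id	family	reference_location	gap_aa	forward_primer	reverse_primer	designed_bp	estimated_bp	validated
1	Unigene53952_All	Unigene31144_All	NRT1/PTR	12-101+208-3'	107	GACTACCAAGGAAATCCAGTGG	CAGGAAGGGCAAGACAACG	721	1042	no
2	Unigene67667_All	Unigene54470_All	NRT1/PTR	5'-177+359-3'	182	TTGGTCCTTTGCTTGGTGC	TTTTCGATGAGGGCGGC	575	1121	no
3	Unigene68619_All	Unigene91547_All	NRT1/PTR	5'-170+164-234	none	CAAAGTGACAAATGGGAAGG	ACAATAGAGTCGTGGTGGAGAT	700	700	yes
4	Unigene60049_All	Unigene54473_All	NRT1/PTR	4-145+136-3'	none	CAGCAGTGGGAAACAACCT	ACCAGAAACCAAGCAAATCA	599	599	yes
5	Unigene31738_All	Unigene31143_All	NRT1/PTR	5'-212+203-3'	none	CGTTGTCTTGCCCTTCCTG	GCCATACTTCTCATATTCTCTGG	695	695	no
6	Unigene63092_All	Unigene71213_All	NRT1/PTR	5'-80+78-3'	none	ATCACACCAGCAGAACACGT	CAAGAACACCCCAAAATCAA	896	896	no
7	Unigene49607_All	Unigene30293_All	NRT1/PTR	59-245+311-3'	66	TGCCTTCCTTAGTGATTCCTAT	AGATTTCCACAACTCCTGCC	768	966	yes
8	Unigene63092_All	Unigene34485_All	NRT1/PTR	5'-80+218-3'	138	GTGGGGTGACCAAGAAGAGA	TAGGAGGATGCTGGCGATG	768	1182	no
9	Unigene85390_All	Unigene23477_All	NRT1/PTR	268-392+466-541	74	ACTAGGGGGATTAGGCCTTT	TGTCGTCGTTTGAACTATGGA	479	701	no
10	Unigene71982_All	Unigene61016_All	NRT1/PTR	5'-321+482-3'	162	TTGGTTTTTTGGCTTCTGC	CCTCCTCCTTTATCTTCTGTGA	560	1046	no
11	Unigene34465_All	Unigene61016_All	NRT1/PTR	5'-430+482-3'	52	CACTTCCACTTACCGCCAC	CGTCCTCCTCCTTTATCTTCTG	731	887	yes
12	Unigene49930_All	Unigene54471_All	NRT1/PTR	41-122+359-3'	237	CACCTTGGGCTTCGCATA	AACGGCAGTCATCATTTCG	563	1274	no
13	Unigene54452_All	Unigene44258_All	NRT2	5'-243+423-463	180	GGGTTTTGTTTCGGGGTG	GGATTAAAGGCTTGTCAGGC	816	1356	no
14	Unigene34113_All	Unigene5588_All	NRT2	5'-258+415-3'	157	GTTCCTCATGCCCCTTGTC	TTGGTGCTTCTCTCGTTTCTAC	465	936	yes
15	Unigene39295_All	Unigene80102_All	NRT2	165-252+381-413	129	TGTTATCCTTAAAACAGGGG	TTGAGTTATGACAGCACCC	437	824	no
16	Unigene136150_All	Unigene132777_All	NRT2	5'-66+402-3'	336	ATTATCAATAGCAAAGCCTC	CAACTGCTCCACTACCCT	417	1425	no
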