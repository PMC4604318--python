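assembly	five_prime_id	three_prime_id	family	five_prime_bp	three_prime_bp	assembled_bp	protein_aa	complete_cds
Assembly 3	Unigene68619_All	Unigene91547_All	NRT1/PTR	762	215	953	293	no
Assembly 4	Unigene60049_All	Unigene54473_All	NRT1/PTR	429	1861	2254	591	no
Assembly 7	Unigene49607_All	Unigene30293_All	NRT1/PTR	561	958	1672	431	no
Assembly 11	Unigene34465_All	Unigene61016_All	NRT1/PTR	1655	695	2498	626	yes
Assembly 14	Unigene34113_All	Unigene5588_All	NRT2	821	747	2030	504	yes
Assembly 6	Unigene11489_All	Unigene63539_All	PHT1	274	249	789	263	no
Assembly 8	Unigene53055_All	Unigene44133_All	PHT1	619	621	1959	534	yes
Assembly 10	Unigene141416_All	Unigene129694_All	PHT3	722	238	1055	345	no
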