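family	min_aa	max_aa
NRT1/PTR	521	636
NRT2	493	557
NRT3	209	210
PHT1	516	542
PHT2	613	613
PHT3	309	375
PHT4	432	541
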