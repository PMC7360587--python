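population	superpopulation	n_AA	n_Aa	n_aa
African	African	623	38	0
American	American	274	71	2
EastAsian	EastAsian	324	158	22
European	European	356	140	7
SouthAsian	SouthAsian	417	70	2
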