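marker	male_allele	enabled
Aa_Y_1	T	true
Aa_Y_2	G	true
Aa_Y_3	G	true
Ce10ay	T	true
Ce12ay	C	true
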