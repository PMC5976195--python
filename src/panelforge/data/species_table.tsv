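species	Aa_mt_1	Aa_mt_4	Aa_mt_5	Ce17mt	Ce19mt
moose	C	C	C	T	G
roe deer	A/C	T	C	T	A
red deer	C	T	T	T	A
fallow deer	C	T	T	C	G
reindeer	C	T	C	T	A
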