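variant	effect_allele	category	beta
rsEX0101	A	blond	1.10
rsEX0101	A	red	0.10
rsEX0101	A	black	-0.90
rsEX0102	T	blond	-0.40
rsEX0102	T	red	2.40
rsEX0102	T	black	-0.20
rsEX0103	C	blond	-0.80
rsEX0103	C	red	-0.30
rsEX0103	C	black	1.60
rsEX0104	G	blond	0.55
rsEX0104	G	red	0.05
rsEX0104	G	black	-0.35
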