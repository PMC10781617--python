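variant	effect_allele	category	beta
rsEX0001	T	blue	-4.30
rsEX0001	T	intermediate	-1.90
rsEX0002	A	blue	0.45
rsEX0002	A	intermediate	0.16
rsEX0003	G	blue	-0.58
rsEX0003	G	intermediate	-0.32
rsEX0004	C	blue	0.27
rsEX0004	C	intermediate	0.20
rsEX0005	T	blue	0.68
rsEX0005	T	intermediate	0.25
rsEX0006	A	blue	-0.15
rsEX0006	A	intermediate	-0.08
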