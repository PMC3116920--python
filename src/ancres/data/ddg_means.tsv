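mutant	ddG_kcal_mol
V43A	1.62
R116H	2.81
C71S	0.29
43/116	5.31
43/71/116	5.41
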