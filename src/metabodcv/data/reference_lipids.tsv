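lipid_class	carbons	double_bonds	rt	mz	annotation
PC	31	0	8.17	720.5657	PC(31:0)
PC	33	1	8.14	790.5627	PC(33:1)
PC	33	1	8.25	790.5631	PC(33:1)
PC	33	0	8.39	748.5876	PC(33:0)
lysoPC	14	0	7.12	512.2960	lysoPC(14:0)
PC-plasmalogen	38	4	8.31	794.5939	PC(P-18:0/20:4)
PC-plasmalogen	38	4	8.36	794.6068	PC(P-20:4/18:0)
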