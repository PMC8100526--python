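mac1	gpiba	Model_I	Model_II	Model_III
K244	D18	0.39	0.77	0.74
E282	K19	0.62	0.66	0.67
S288	D235	0.23	0.52	0.57
E242	K19	0.35	0.44	0.43
E252	S39	0.31	0.44	0.53
Y251	R64	0.17	0.34	0.53
K278	E40	0.67	0.32	0.28
E261	K237	0	0.54	0.59
R216	D63	0	0.31	0.25
K278	Q66	0	0.27	0.23
D259	K231	0	0.23	0.15
K278	R64	0	0.16	0.12
H294	K231	0	0.16	0.2
K289	K231	0	0.16	0.18
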