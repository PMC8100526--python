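mac1	gpiba	0	25	50	75
E252	K37	0.08	0.19	0.43	0.03
E252	S39	0.44	0.67	0.83	0.39
E252	R64	0.10	0.74	0.48	0.49
E261	K237	0.54	0.58	0.57	0.39
K278	E40	0.32	0.62	0.55	0.56
S288	D235	0.52	0.79	0.77	0.62
K244	D18	0.77	0.61	0.66	0.58
Y251	R64	0.34	0.14	0.28	0.16
D259	K231	0.23	0.48	0.25	0.33
E243	K19	0.44	0.37	0.24	0.19
E282	K19	0.66	0.64	0.47	0.48
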