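descriptor	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
net_charge_index	0.007187	-0.036610	-0.023820	0.006802	0.037552	0.179052	-0.010690	0.021631	0.017708	0.051672	0.002683	0.005392	0.239531	0.049211	0.043587	0.004627	0.003352	0.057004	0.037977	0.023599
polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
polarizability	0.046	0.128	0.105	0.151	0.290	0.000	0.230	0.186	0.219	0.186	0.221	0.134	0.131	0.180	0.291	0.062	0.108	0.140	0.409	0.298
solvent_accessible_surface_area	1.181	1.461	1.587	1.862	2.228	0.881	2.025	1.810	2.258	1.931	2.034	1.655	1.468	1.932	2.560	1.298	1.525	1.645	2.663	2.368
side_chain_volume	27.5	44.6	40.0	62.0	115.5	0.0	79.0	93.5	100.0	93.5	94.1	58.7	41.9	80.7	105.0	29.3	51.3	71.5	145.5	117.3
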