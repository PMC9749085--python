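# Equilibrium geometrical parameters of the formic acid dimer: literature
# benchmark set.  Bond lengths in Angstroms, angles in degrees.  kind is
# "length" or "angle".  Columns: coupled-cluster reference (default/tight
# settings), an earlier permutationally-invariant-polynomial fit (pip), and
# the three neural-network potential stages.
parameter	kind	ab_initio_default	ab_initio_tight	pip	nnp_stage1	nnp_stage2	nnp_stage3
r(O-H)	length	0.9934	0.9932	0.9927	0.9945	0.9925	0.9936
r(C-H)	length	1.0929	1.0930	1.0929	1.0927	1.0937	1.0927
r(C-O)	length	1.3113	1.3114	1.3116	1.3104	1.3121	1.3112
r(O...O)	length	2.6748	2.6758	2.6778	2.6729	2.6791	2.6709
r(C=O)	length	1.2177	1.2176	1.2174	1.2192	1.2172	1.2178
a(OC-O)	angle	126.14	126.14	126.15	126.26	126.13	126.13
a(OC-H)	angle	122.02	122.03	122.05	122.04	122.15	121.99
a(C-O-H)	angle	109.77	109.76	109.73	109.42	109.93	109.79
a(O-H...O)	angle	178.93	178.93	178.95	179.51	179.01	178.86
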