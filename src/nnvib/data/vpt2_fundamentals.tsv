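# VPT2 anharmonic fundamentals (cm-1) of the formic acid dimer: literature
# benchmark set.  Columns: direct coupled-cluster VPT2 (tight settings), the
# final neural-network potential, and gas-phase experiment (blank where no
# experimental fundamental is established).  resonance=1 marks fundamentals
# involved in a Fermi resonance (nu3 with nu4+nu8, nu14 with nu12+nu23,
# nu22 with nu10+nu15).
mode	ab_initio	nnp	experiment	resonance
1	2909	2920		0
2	2942	2948		0
3	1672	1677	1664	1
4	1431	1433	1430	0
5	1375	1375	1375	0
6	1225	1229	1224	0
7	679	682	681	0
8	194	197	194	0
9	157	164	161	0
10	1061	1058	1058	0
11	923	934	911	0
12	241	247	242	0
13	1072	1074	1069	0
14	959	964	939	1
15	162	166	168	0
16	67	68	69	0
17	3044	3041		0
18	2935	2941		0
19	1741	1745	1741	0
20	1406	1416	1407	0
21	1372	1375	1372	0
22	1234	1233	1234	1
23	704	706	708	0
24	262	264	264	0
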