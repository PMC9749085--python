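# Harmonic frequencies (cm-1) of the formic acid dimer: literature benchmark set.
# Columns: three neural-network potential refinement stages and the reference
# coupled-cluster (fc-CCSD(T)-F12a/haTZ) values with default and tight
# convergence settings.
mode	nnp_stage1	nnp_stage2	nnp_stage3	ab_initio_default	ab_initio_tight
1	3218	3212	3209	3203	3207
2	3060	3077	3103	3105	3103
3	1708	1723	1722	1717	1718
4	1443	1485	1486	1484	1482
5	1376	1417	1410	1413	1411
6	1254	1249	1257	1257	1255
7	689	681	688	688	686
8	216	215	214	211	210
9	164	173	167	171	170
10	1073	1083	1083	1085	1083
11	980	960	957	960	955
12	257	241	257	258	249
13	1128	1106	1109	1102	1101
14	937	983	979	986	985
15	213	161	180	186	173
16	68	71	71	76	68
17	3324	3323	3312	3305	3309
18	3108	3085	3100	3101	3099
19	1773	1783	1784	1782	1782
20	1411	1459	1459	1456	1453
21	1358	1414	1410	1405	1407
22	1208	1247	1260	1260	1260
23	704	718	712	716	715
24	281	275	275	278	276
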