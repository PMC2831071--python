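# Detailed derivation of the TP53 / MDM2 regulatory-loop theorem
# 0 |- (TP53 & TP53 & MDM2_gene & U & P) -> d(TP53)
1	TP53 & TP53 & MDM2_gene & U & P	IA
2	TP53	AndE:1
3	TP53	AndE:1
4	MDM2_gene	AndE:1
5	U	AndE:1
6	P	AndE:1
7	TP53 & MDM2_gene	AndI:2,4
8	TP53 & MDM2_gene -> TP53*MDM2_gene	EVF:loop1
9	TP53*MDM2_gene	ArrowE:8,7
10	TP53*MDM2_gene -> MDM2	EVF:loop2
11	MDM2	ArrowE:10,9
12	MDM2 & TP53	AndI:3,11
13	MDM2 & TP53 -> MDM2*TP53	EVF:loop3
14	MDM2*TP53	ArrowE:13,12
15	(MDM2*TP53) & U	AndI:5,14
16	(MDM2*TP53) & U -> (MDM2*TP53)*U	EVF:loop4
17	(MDM2*TP53)*U	ArrowE:16,15
18	(MDM2*TP53)*U -> MDM2 & (TP53*U)	EVF:loop5
19	MDM2 & (TP53*U)	ArrowE:18,17
20	TP53*U	AndE:19
21	(TP53*U) & P	AndI:6,20
22	(TP53*U) & P -> (TP53*U)*P	EVF:loop6
23	(TP53*U)*P	ArrowE:22,21
24	(TP53*U)*P -> d(TP53) & U & P	EVF:loop7
25	d(TP53) & U & P	ArrowE:24,23
26	d(TP53)	AndE:25
27	(TP53 & TP53 & MDM2_gene & U & P) -> d(TP53)	ArrowI:1,1-26
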