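# Detailed derivation of the feed-forward-loop theorem
# 0 |- (A_gene & A_gene & B_gene & C_gene & RA & RA & RB) -> C
# Note the A_gene activation rules (ffl1, ffl2) are introduced twice:
# EVF lines are resources and each application needs its own line.
1	A_gene & A_gene & B_gene & C_gene & RA & RA & RB	IA
2	A_gene	AndE:1
3	A_gene	AndE:1
4	B_gene	AndE:1
5	C_gene	AndE:1
6	RA	AndE:1
7	RA	AndE:1
8	RB	AndE:1
9	A_gene & RA	AndI:2,6
10	A_gene & RA -> A_gene*RA	EVF:ffl1
11	A_gene*RA	ArrowE:10,9
12	A_gene*RA -> A	EVF:ffl2
13	A	ArrowE:12,11
14	A & RB	AndI:8,13
15	A & RB -> A*RB	EVF:ffl3
16	A*RB	ArrowE:15,14
17	(A*RB) & B_gene	AndI:4,16
18	(A*RB) & B_gene -> (A*RB)*B_gene	EVF:ffl4
19	(A*RB)*B_gene	ArrowE:18,17
20	(A*RB)*B_gene -> B	EVF:ffl5
21	B	ArrowE:20,19
22	A_gene & RA	AndI:3,7
23	A_gene & RA -> A_gene*RA	EVF:ffl1
24	A_gene*RA	ArrowE:23,22
25	A_gene*RA -> A	EVF:ffl2
26	A	ArrowE:25,24
27	A & B	AndI:21,26
28	A & B -> A*B	EVF:ffl6
29	A*B	ArrowE:28,27
30	(A*B) & C_gene	AndI:5,29
31	(A*B) & C_gene -> (A*B)*C_gene	EVF:ffl7
32	(A*B)*C_gene	ArrowE:31,30
33	(A*B)*C_gene -> C	EVF:ffl8
34	C	ArrowE:33,32
35	(A_gene & A_gene & B_gene & C_gene & RA & RA & RB) -> C	ArrowI:1,1-34
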