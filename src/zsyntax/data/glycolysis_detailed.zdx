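# Detailed derivation of the glycolysis theorem
# 0 |- (Glc & HK & GPI & PFK & ATP & ATP) -> F1,6P
1	Glc & HK & GPI & PFK & ATP & ATP	IA
2	Glc & HK	AndE:1
3	GPI	AndE:1
4	PFK	AndE:1
5	ATP	AndE:1
6	ATP	AndE:1
7	Glc & HK -> Glc*HK	EVF:gly1
8	Glc*HK	ArrowE:7,2
9	(Glc*HK) & ATP	AndI:5,8
10	(Glc*HK) & ATP -> (Glc*HK)*ATP	EVF:gly2
11	(Glc*HK)*ATP	ArrowE:10,9
12	(Glc*HK)*ATP -> G6P & HK & ADP	EVF:gly3
13	G6P & HK & ADP	ArrowE:12,11
14	G6P	AndE:13
15	HK	AndE:13
16	ADP	AndE:13
17	G6P & GPI	AndI:3,14
18	G6P & GPI -> G6P*GPI	EVF:gly4
19	G6P*GPI	ArrowE:18,17
20	G6P*GPI -> F6P & GPI	EVF:gly5
21	F6P & GPI	ArrowE:20,19
22	F6P	AndE:21
23	GPI	AndE:21
24	F6P & PFK	AndI:4,22
25	F6P & PFK -> F6P*PFK	EVF:gly6
26	F6P*PFK	ArrowE:25,24
27	(F6P*PFK) & ATP	AndI:6,26
28	(F6P*PFK) & ATP -> (F6P*PFK)*ATP	EVF:gly7
29	(F6P*PFK)*ATP	ArrowE:28,27
30	(F6P*PFK)*ATP -> F1,6P & PFK & ADP	EVF:gly8
31	F1,6P & PFK & ADP	ArrowE:30,29
32	F1,6P	AndE:31
33	(Glc & HK & GPI & PFK & ATP & ATP) -> F1,6P	ArrowI:1,1-32
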