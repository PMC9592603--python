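no,np,cell,dg_np_v_kj_mol,dg_barrier_v_m_kj_mol,size_rank
1,C1(methoxy),RAW 264.7,779,1171,1
2,C6S(hexyl),RAW 264.7,571,1185,1
3,"C6B-2(3,3-dimethylbutyl)",RAW 264.7,579,1199,1
4,C6C(cyclohexyl),RAW 264.7,577,1165,1
5,C6E-1(5-hexenyl),RAW 264.7,570,1165,1
6,C6E-2(2-hexenyl),RAW 264.7,607,1237,1
7,C6A(phenyl),RAW 264.7,682,1302,1
8,C12S(dodecyl),RAW 264.7,455,1274,1
9,C12B(2-butyloctyl),RAW 264.7,453,1270,1
10,C12C(cyclododecyl),RAW 264.7,436,1194,1
11,C12A-1(5-naphthybutyl),RAW 264.7,505,1250,1
12,C12A-2(7-phenylheptyl),RAW 264.7,458,1199,1
13,C1(methoxy),C166,779,1171,1
14,C6S(hexyl),C166,571,1185,1
15,"C6B-2(3,3-dimethylbutyl)",C166,579,1199,1
16,C6C(cyclohexyl),C166,577,1165,1
17,C6E-1(5-hexenyl),C166,570,1165,1
18,C6E-2(2-hexenyl),C166,607,1237,1
19,C6A(phenyl),C166,682,1302,1
20,C12S(dodecyl),C166,455,1274,1
21,C12B(2-butyloctyl),C166,453,1270,1
22,C12C(cyclododecyl),C166,436,1194,1
23,C12A-1(5-naphthybutyl),C166,505,1250,1
24,C12A-2(7-phenylheptyl),C166,458,1199,1
25,C1(methoxy),Hela,779,1171,1
26,C6S(hexyl),Hela,571,1185,1
27,"C6B-2(3,3-dimethylbutyl)",Hela,579,1199,1
28,C6C(cyclohexyl),Hela,577,1165,1
29,C6E-1(5-hexenyl),Hela,570,1165,1
30,C6E-2(2-hexenyl),Hela,607,1237,1
31,C6A(phenyl),Hela,682,1302,1
32,C12S(dodecyl),Hela,455,1274,1
33,C12B(2-butyloctyl),Hela,453,1270,1
34,C12C(cyclododecyl),Hela,436,1194,1
35,C12A-1(5-naphthybutyl),Hela,505,1250,1
36,C12A-2(7-phenylheptyl),Hela,458,1199,1
37,Citrate,U937,675,667,1
38,Citrate,U937,1259,1243,2
39,Citrate,U937,2132,2105,3
40,Cysteamine,U937,346,624,1
41,Cysteamine,U937,744,1343,2
42,Cysteamine,U937,1225,2212,3
43,L-cysteine,U937,591,753,1
44,L-cysteine,U937,990,1260,2
45,L-cysteine,U937,1776,2260,3
46,PEG,U937,1266,1177,1
47,PEG,U937,1789,1663,2
48,PEG,U937,2746,2552,3
49,Transferrin,STO,477,648,1
50,Transferrin,STO,1022,1388,2
51,Transferrin,STO,1703,2314,3
52,Transferrin,STO,2520,3425,4
53,Transferrin,STO,3406,4628,5
54,Transferrin,SNB19,477,648,1
55,Transferrin,SNB19,1022,1388,2
56,Transferrin,SNB19,1703,2314,3
57,Transferrin,SNB19,2520,3425,4
58,Transferrin,SNB19,3406,4628,5
59,Transferrin,Hela,477,648,1
60,Transferrin,Hela,1022,1388,2
61,Transferrin,Hela,1703,2314,3
62,Transferrin,Hela,2520,3425,4
63,Transferrin,Hela,3406,4628,5
64,D-penicillamine,Hela,248,370,1
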