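id,name,unit,min,max
1,Kp_lung(CPT-11),-,0.1,10
2,Kp_lung(SN-38),-,0.1,10
3,Kp_lung(SN-38G),-,0.1,10
4,Kp_lung(NPC),-,0.1,10
5,Kp_lung(APC),-,0.1,10
6,Kp_heart(CPT-11),-,0.1,10
7,Kp_heart(SN-38),-,0.1,10
8,Kp_heart(SN-38G),-,0.1,10
9,Kp_heart(NPC),-,0.1,10
10,Kp_heart(APC),-,0.1,10
11,Kp_brain(CPT-11),-,0.1,10
12,Kp_brain(SN-38),-,0.1,10
13,Kp_brain(SN-38G),-,0.1,10
14,Kp_brain(NPC),-,0.1,10
15,Kp_brain(APC),-,0.1,10
16,Kp_muscle(CPT-11),-,0.1,10
17,Kp_muscle(SN-38),-,0.1,10
18,Kp_muscle(SN-38G),-,0.1,10
19,Kp_muscle(NPC),-,0.1,10
20,Kp_muscle(APC),-,0.1,10
21,Kp_adipose(CPT-11),-,0.1,10
22,Kp_adipose(SN-38),-,0.1,10
23,Kp_adipose(SN-38G),-,0.1,10
24,Kp_adipose(NPC),-,0.1,10
25,Kp_adipose(APC),-,0.1,10
26,Kp_skin(CPT-11),-,0.1,10
27,Kp_skin(SN-38),-,0.1,10
28,Kp_skin(SN-38G),-,0.1,10
29,Kp_skin(NPC),-,0.1,10
30,Kp_skin(APC),-,0.1,10
31,Kp_bone(CPT-11),-,0.1,10
32,Kp_bone(SN-38),-,0.1,10
33,Kp_bone(SN-38G),-,0.1,10
34,Kp_bone(NPC),-,0.1,10
35,Kp_bone(APC),-,0.1,10
36,Kp_kidney(CPT-11),-,0.1,10
37,Kp_kidney(SN-38),-,0.1,10
38,Kp_kidney(SN-38G),-,0.1,10
39,Kp_kidney(NPC),-,0.1,10
40,Kp_kidney(APC),-,0.1,10
41,Kp_spleen(CPT-11),-,0.1,10
42,Kp_spleen(SN-38),-,0.1,10
43,Kp_spleen(SN-38G),-,0.1,10
44,Kp_spleen(NPC),-,0.1,10
45,Kp_spleen(APC),-,0.1,10
46,Kp_pancreas(CPT-11),-,0.1,10
47,Kp_pancreas(SN-38),-,0.1,10
48,Kp_pancreas(SN-38G),-,0.1,10
49,Kp_pancreas(NPC),-,0.1,10
50,Kp_pancreas(APC),-,0.1,10
51,Kp_stomach(CPT-11),-,0.1,10
52,Kp_stomach(SN-38),-,0.1,10
53,Kp_stomach(SN-38G),-,0.1,10
54,Kp_stomach(NPC),-,0.1,10
55,Kp_stomach(APC),-,0.1,10
56,Kp_small_intestine(CPT-11),-,0.1,10
57,Kp_small_intestine(SN-38),-,0.1,10
58,Kp_small_intestine(SN-38G),-,0.1,10
59,Kp_small_intestine(NPC),-,0.1,10
60,Kp_small_intestine(APC),-,0.1,10
61,Kp_large_intestine(CPT-11),-,0.1,10
62,Kp_large_intestine(SN-38),-,0.1,10
63,Kp_large_intestine(SN-38G),-,0.1,10
64,Kp_large_intestine(NPC),-,0.1,10
65,Kp_large_intestine(APC),-,0.1,10
66,Kp_liver(CPT-11),-,0.1,10
67,Kp_liver(SN-38),-,0.1,10
68,Kp_liver(SN-38G),-,0.1,10
69,Kp_liver(NPC),-,0.1,10
70,Kp_liver(APC),-,0.1,10
71,CL_r(CPT-11),ml/min/kg,0.1,10
72,CL_r(SN-38),ml/min/kg,0.01,1
73,CL_r(SN-38G),ml/min/kg,0.01,1
74,CL_r(NPC),ml/min/kg,0.01,1
75,CL_r(APC),ml/min/kg,0.01,1
76,CL_bile(CPT-11),ml/min/kg,0.1,10
77,CL_bile(SN-38),ml/min/kg,0.1,10
78,CL_bile(SN-38G),ml/min/kg,0.1,10
79,CL_bile(NPC),ml/min/kg,0.1,10
80,CL_bile(APC),ml/min/kg,0.1,10
81,CL_CES1,ml/min/kg,0.1,10
82,CL_CES2,ml/min/kg,0.1,10
83,CL_3A4_1,ml/min/kg,0.1,10
84,CL_3A4_2,ml/min/kg,0.1,10
85,CL_UGT,ml/min/kg,0.1,10
86,k_bile(CPT-11),/min,0.001,0.1
87,k_bile(SN-38),/min,0.001,0.1
88,k_bile(SN-38G),/min,0.001,0.1
89,k_bile(NPC),/min,0.001,0.1
90,k_bile(APC),/min,0.001,0.1
91,k_a(CPT-11),/min,0.0001,0.01
92,k_a(SN-38),/min,0.0001,0.01
93,k_a(SN-38G),/min,0.0001,0.01
94,k_a(NPC),/min,0.0001,0.01
95,k_a(APC),/min,0.0001,0.01
96,k_li(CPT-11),/min,0.0001,0.01
97,k_li(SN-38),/min,0.0001,0.01
98,k_li(SN-38G),/min,0.0001,0.01
99,k_li(NPC),/min,0.0001,0.01
100,k_li(APC),/min,0.0001,0.01
101,k_feces(CPT-11),/min,0.0001,0.01
102,k_feces(SN-38),/min,0.0001,0.01
103,k_feces(SN-38G),/min,0.0001,0.01
104,k_feces(NPC),/min,0.0001,0.01
105,k_feces(APC),/min,0.0001,0.01
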