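region_id,region_name,hemisphere,lobe
1,Precentral_L,left,central
2,Precentral_R,right,central
3,Frontal_Sup_L,left,frontal
4,Frontal_Sup_R,right,frontal
5,Frontal_Sup_Orb_L,left,frontal
6,Frontal_Sup_Orb_R,right,frontal
7,Frontal_Mid_L,left,frontal
8,Frontal_Mid_R,right,frontal
9,Frontal_Mid_Orb_L,left,frontal
10,Frontal_Mid_Orb_R,right,frontal
11,Frontal_Inf_Oper_L,left,frontal
12,Frontal_Inf_Oper_R,right,frontal
13,Frontal_Inf_Tri_L,left,frontal
14,Frontal_Inf_Tri_R,right,frontal
15,Frontal_Inf_Orb_L,left,frontal
16,Frontal_Inf_Orb_R,right,frontal
17,Rolandic_Oper_L,left,central
18,Rolandic_Oper_R,right,central
19,Supp_Motor_Area_L,left,frontal
20,Supp_Motor_Area_R,right,frontal
21,Olfactory_L,left,frontal
22,Olfactory_R,right,frontal
23,Frontal_Sup_Medial_L,left,frontal
24,Frontal_Sup_Medial_R,right,frontal
25,Frontal_Med_Orb_L,left,frontal
26,Frontal_Med_Orb_R,right,frontal
27,Rectus_L,left,frontal
28,Rectus_R,right,frontal
29,Insula_L,left,insula
30,Insula_R,right,insula
31,Cingulum_Ant_L,left,limbic
32,Cingulum_Ant_R,right,limbic
33,Cingulum_Mid_L,left,limbic
34,Cingulum_Mid_R,right,limbic
35,Cingulum_Post_L,left,limbic
36,Cingulum_Post_R,right,limbic
37,Hippocampus_L,left,limbic
38,Hippocampus_R,right,limbic
39,ParaHippocampal_L,left,limbic
40,ParaHippocampal_R,right,limbic
41,Amygdala_L,left,subcortical
42,Amygdala_R,right,subcortical
43,Calcarine_L,left,occipital
44,Calcarine_R,right,occipital
45,Cuneus_L,left,occipital
46,Cuneus_R,right,occipital
47,Lingual_L,left,occipital
48,Lingual_R,right,occipital
49,Occipital_Sup_L,left,occipital
50,Occipital_Sup_R,right,occipital
51,Occipital_Mid_L,left,occipital
52,Occipital_Mid_R,right,occipital
53,Occipital_Inf_L,left,occipital
54,Occipital_Inf_R,right,occipital
55,Fusiform_L,left,occipital
56,Fusiform_R,right,occipital
57,Postcentral_L,left,central
58,Postcentral_R,right,central
59,Parietal_Sup_L,left,parietal
60,Parietal_Sup_R,right,parietal
61,Parietal_Inf_L,left,parietal
62,Parietal_Inf_R,right,parietal
63,SupraMarginal_L,left,parietal
64,SupraMarginal_R,right,parietal
65,Angular_L,left,parietal
66,Angular_R,right,parietal
67,Precuneus_L,left,parietal
68,Precuneus_R,right,parietal
69,Paracentral_Lobule_L,left,central
70,Paracentral_Lobule_R,right,central
71,Caudate_L,left,subcortical
72,Caudate_R,right,subcortical
73,Putamen_L,left,subcortical
74,Putamen_R,right,subcortical
75,Pallidum_L,left,subcortical
76,Pallidum_R,right,subcortical
77,Thalamus_L,left,subcortical
78,Thalamus_R,right,subcortical
79,Heschl_L,left,temporal
80,Heschl_R,right,temporal
81,Temporal_Sup_L,left,temporal
82,Temporal_Sup_R,right,temporal
83,Temporal_Pole_Sup_L,left,limbic
84,Temporal_Pole_Sup_R,right,limbic
85,Temporal_Mid_L,left,temporal
86,Temporal_Mid_R,right,temporal
87,Temporal_Pole_Mid_L,left,limbic
88,Temporal_Pole_Mid_R,right,limbic
89,Temporal_Inf_L,left,temporal
90,Temporal_Inf_R,right,temporal
91,Cerebelum_Crus1_L,left,cerebellum
92,Cerebelum_Crus1_R,right,cerebellum
93,Cerebelum_Crus2_L,left,cerebellum
94,Cerebelum_Crus2_R,right,cerebellum
95,Cerebelum_3_L,left,cerebellum
96,Cerebelum_3_R,right,cerebellum
97,Cerebelum_4_5_L,left,cerebellum
98,Cerebelum_4_5_R,right,cerebellum
99,Cerebelum_6_L,left,cerebellum
100,Cerebelum_6_R,right,cerebellum
101,Cerebelum_7b_L,left,cerebellum
102,Cerebelum_7b_R,right,cerebellum
103,Cerebelum_8_L,left,cerebellum
104,Cerebelum_8_R,right,cerebellum
105,Cerebelum_9_L,left,cerebellum
106,Cerebelum_9_R,right,cerebellum
107,Cerebelum_10_L,left,cerebellum
108,Cerebelum_10_R,right,cerebellum
109,Vermis_1_2,midline,vermis
110,Vermis_3,midline,vermis
111,Vermis_4_5,midline,vermis
112,Vermis_6,midline,vermis
113,Vermis_7,midline,vermis
114,Vermis_8,midline,vermis
115,Vermis_9,midline,vermis
116,Vermis_10,midline,vermis
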