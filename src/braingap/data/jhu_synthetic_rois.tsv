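roi_id	name	hemisphere
1	superior_frontal_gyrus	left
2	middle_frontal_gyrus_dpfc	left
3	middle_frontal_gyrus_orbital	left
4	inferior_frontal_gyrus_opercularis	left
5	inferior_frontal_gyrus_orbitalis	left
6	inferior_frontal_gyrus_triangularis	left
7	precentral_gyrus	left
8	lateral_fronto_orbital_gyrus	left
9	middle_fronto_orbital_gyrus	left
10	gyrus_rectus	left
11	supplementary_motor_area	left
12	frontal_pole	left
13	medial_frontal_gyrus	left
14	paracentral_lobule	left
15	central_operculum	left
16	frontal_operculum	left
17	superior_temporal_gyrus	left
18	posterior_superior_temporal_gyrus	left
19	middle_temporal_gyrus	left
20	posterior_middle_temporal_gyrus	left
21	inferior_temporal_gyrus	left
22	posterior_inferior_temporal_gyrus	left
23	fusiform_gyrus	left
24	parahippocampal_gyrus	left
25	entorhinal_area	left
26	temporal_pole	left
27	heschl_gyrus	left
28	planum_temporale	left
29	planum_polare	left
30	postcentral_gyrus	left
31	superior_parietal_lobule	left
32	supramarginal_gyrus	left
33	angular_gyrus	left
34	precuneus	left
35	parietal_operculum	left
36	superior_occipital_gyrus	left
37	middle_occipital_gyrus	left
38	inferior_occipital_gyrus	left
39	cuneus	left
40	lingual_gyrus	left
41	insular	left
42	anterior_cingulate_gyrus	left
43	middle_cingulate_gyrus	left
44	posterior_cingulate_gyrus	left
45	retrosplenial_cortex	left
46	hippocampus	left
47	amygdala	left
48	olfactory_area	left
49	caudate_nucleus	left
50	putamen	left
51	globus_pallidus	left
52	thalamus	left
53	nucleus_accumbens	left
54	substantia_nigra	left
55	red_nucleus	left
56	mammillary_body	left
57	hypothalamus	left
58	basal_forebrain	left
59	corticospinal_tract	left
60	cerebral_peduncle	left
61	anterior_limb_of_internal_capsule	left
62	posterior_limb_of_internal_capsule	left
63	retrolenticular_part_of_internal_capsule	left
64	anterior_corona_radiata	left
65	superior_corona_radiata	left
66	posterior_corona_radiata	left
67	posterior_thalamic_radiation	left
68	sagittal_stratum	left
69	external_capsule	left
70	cingulum_cingulate_part	left
71	cingulum_hippocampal_part	left
72	fornix_cres	left
73	stria_terminalis	left
74	superior_longitudinal_fasciculus	left
75	inferior_longitudinal_fasciculus	left
76	inferior_fronto_occipital_fasciculus	left
77	uncinate_fasciculus	left
78	superior_fronto_occipital_fasciculus	left
79	tapetum	left
80	medial_lemniscus	left
81	inferior_cerebellar_peduncle	left
82	superior_cerebellar_peduncle	left
83	optic_tract	left
84	optic_radiation	left
85	anterior_thalamic_radiation	left
86	corticopontine_tract	left
87	frontal_white_matter	left
88	parietal_white_matter	left
89	temporal_white_matter	left
90	occipital_white_matter	left
91	periventricular_white_matter	left
92	genu_of_corpus_callosum	left
93	body_of_corpus_callosum	left
94	splenium_of_corpus_callosum	left
95	superior_frontal_gyrus	right
96	middle_frontal_gyrus_dpfc	right
97	middle_frontal_gyrus_orbital	right
98	inferior_frontal_gyrus_opercularis	right
99	inferior_frontal_gyrus_orbitalis	right
100	inferior_frontal_gyrus_triangularis	right
101	precentral_gyrus	right
102	lateral_fronto_orbital_gyrus	right
103	middle_fronto_orbital_gyrus	right
104	gyrus_rectus	right
105	supplementary_motor_area	right
106	frontal_pole	right
107	medial_frontal_gyrus	right
108	paracentral_lobule	right
109	central_operculum	right
110	frontal_operculum	right
111	superior_temporal_gyrus	right
112	posterior_superior_temporal_gyrus	right
113	middle_temporal_gyrus	right
114	posterior_middle_temporal_gyrus	right
115	inferior_temporal_gyrus	right
116	posterior_inferior_temporal_gyrus	right
117	fusiform_gyrus	right
118	parahippocampal_gyrus	right
119	entorhinal_area	right
120	temporal_pole	right
121	heschl_gyrus	right
122	planum_temporale	right
123	planum_polare	right
124	postcentral_gyrus	right
125	superior_parietal_lobule	right
126	supramarginal_gyrus	right
127	angular_gyrus	right
128	precuneus	right
129	parietal_operculum	right
130	superior_occipital_gyrus	right
131	middle_occipital_gyrus	right
132	inferior_occipital_gyrus	right
133	cuneus	right
134	lingual_gyrus	right
135	insular	right
136	anterior_cingulate_gyrus	right
137	middle_cingulate_gyrus	right
138	posterior_cingulate_gyrus	right
139	retrosplenial_cortex	right
140	hippocampus	right
141	amygdala	right
142	olfactory_area	right
143	caudate_nucleus	right
144	putamen	right
145	globus_pallidus	right
146	thalamus	right
147	nucleus_accumbens	right
148	substantia_nigra	right
149	red_nucleus	right
150	mammillary_body	right
151	hypothalamus	right
152	basal_forebrain	right
153	corticospinal_tract	right
154	cerebral_peduncle	right
155	anterior_limb_of_internal_capsule	right
156	posterior_limb_of_internal_capsule	right
157	retrolenticular_part_of_internal_capsule	right
158	anterior_corona_radiata	right
159	superior_corona_radiata	right
160	posterior_corona_radiata	right
161	posterior_thalamic_radiation	right
162	sagittal_stratum	right
163	external_capsule	right
164	cingulum_cingulate_part	right
165	cingulum_hippocampal_part	right
166	fornix_cres	right
167	stria_terminalis	right
168	superior_longitudinal_fasciculus	right
169	inferior_longitudinal_fasciculus	right
170	inferior_fronto_occipital_fasciculus	right
171	uncinate_fasciculus	right
172	superior_fronto_occipital_fasciculus	right
173	tapetum	right
174	medial_lemniscus	right
175	inferior_cerebellar_peduncle	right
176	superior_cerebellar_peduncle	right
177	optic_tract	right
178	optic_radiation	right
179	anterior_thalamic_radiation	right
180	corticopontine_tract	right
181	frontal_white_matter	right
182	parietal_white_matter	right
183	temporal_white_matter	right
184	occipital_white_matter	right
185	periventricular_white_matter	right
186	genu_of_corpus_callosum	right
187	body_of_corpus_callosum	right
188	splenium_of_corpus_callosum	right
189	cerebellar_vermis	none
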