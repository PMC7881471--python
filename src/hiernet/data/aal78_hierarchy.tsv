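layer4_index	layer4_name	hemisphere	layer3_index	layer3_name	layer2_index	layer2_name
1	Precentral gyrus	L	1	Central region: precentral gyrus	1	Central region
2	Precentral gyrus	R	2	Central region: precentral gyrus	2	Central region
3	Superior frontal gyrus (dorsal)	L	7	Frontal lobe: lateral surface	3	Frontal lobe
4	Superior frontal gyrus (dorsal)	R	8	Frontal lobe: lateral surface	4	Frontal lobe
5	Orbitofrontal cortex (superior)	L	11	Frontal lobe: orbital surface	3	Frontal lobe
6	Orbitofrontal cortex (superior)	R	12	Frontal lobe: orbital surface	4	Frontal lobe
7	Middle frontal gyrus	L	7	Frontal lobe: lateral surface	3	Frontal lobe
8	Middle frontal gyrus	R	8	Frontal lobe: lateral surface	4	Frontal lobe
9	Orbitofrontal cortex (middle)	L	11	Frontal lobe: orbital surface	3	Frontal lobe
10	Orbitofrontal cortex (middle)	R	12	Frontal lobe: orbital surface	4	Frontal lobe
11	Inferior frontal gyrus (opercular)	L	7	Frontal lobe: lateral surface	3	Frontal lobe
12	Inferior frontal gyrus (opercular)	R	8	Frontal lobe: lateral surface	4	Frontal lobe
13	Inferior frontal gyrus (triangular)	L	7	Frontal lobe: lateral surface	3	Frontal lobe
14	Inferior frontal gyrus (triangular)	R	8	Frontal lobe: lateral surface	4	Frontal lobe
15	Orbitofrontal cortex (inferior)	L	11	Frontal lobe: orbital surface	3	Frontal lobe
16	Orbitofrontal cortex (inferior)	R	12	Frontal lobe: orbital surface	4	Frontal lobe
17	Rolandic operculum	L	5	Central region: Rolandic operculum	1	Central region
18	Rolandic operculum	R	6	Central region: Rolandic operculum	2	Central region
19	Supplementary motor area	L	9	Frontal lobe: medial surface	3	Frontal lobe
20	Supplementary motor area	R	10	Frontal lobe: medial surface	4	Frontal lobe
21	Olfactory	L	11	Frontal lobe: orbital surface	3	Frontal lobe
22	Olfactory	R	12	Frontal lobe: orbital surface	4	Frontal lobe
23	Superior frontal gyrus (medial)	L	9	Frontal lobe: medial surface	3	Frontal lobe
24	Superior frontal gyrus (medial)	R	10	Frontal lobe: medial surface	4	Frontal lobe
25	Orbitofrontal cortex (medial)	L	11	Frontal lobe: orbital surface	3	Frontal lobe
26	Orbitofrontal cortex (medial)	R	12	Frontal lobe: orbital surface	4	Frontal lobe
27	Rectus gyrus	L	11	Frontal lobe: orbital surface	3	Frontal lobe
28	Rectus gyrus	R	12	Frontal lobe: orbital surface	4	Frontal lobe
29	Insula	L	35	Insula: insula	13	Insula
30	Insula	R	36	Insula: insula	14	Insula
31	Anterior cingulate gyrus	L	27	Limbic lobe: anterior cingulate gyrus	11	Limbic lobe
32	Anterior cingulate gyrus	R	28	Limbic lobe: anterior cingulate gyrus	12	Limbic lobe
33	Middle cingulate gyrus	L	29	Limbic lobe: middle cingulate gyrus	11	Limbic lobe
34	Middle cingulate gyrus	R	30	Limbic lobe: middle cingulate gyrus	12	Limbic lobe
35	Posterior cingulate gyrus	L	31	Limbic lobe: posterior cingulate gyrus	11	Limbic lobe
36	Posterior cingulate gyrus	R	32	Limbic lobe: posterior cingulate gyrus	12	Limbic lobe
37	Parahippocampal gyrus	L	33	Limbic lobe: parahippocampal gyrus	11	Limbic lobe
38	Parahippocampal gyrus	R	34	Limbic lobe: parahippocampal gyrus	12	Limbic lobe
39	Calcarine cortex	L	21	Occipital lobe: medial and inferior surfaces	9	Occipital lobe
40	Calcarine cortex	R	22	Occipital lobe: medial and inferior surfaces	10	Occipital lobe
41	Cuneus	L	21	Occipital lobe: medial and inferior surfaces	9	Occipital lobe
42	Cuneus	R	22	Occipital lobe: medial and inferior surfaces	10	Occipital lobe
43	Lingual gyrus	L	21	Occipital lobe: medial and inferior surfaces	9	Occipital lobe
44	Lingual gyrus	R	22	Occipital lobe: medial and inferior surfaces	10	Occipital lobe
45	Superior occipital gyrus	L	19	Occipital lobe: lateral surface	9	Occipital lobe
46	Superior occipital gyrus	R	20	Occipital lobe: lateral surface	10	Occipital lobe
47	Middle occipital gyrus	L	19	Occipital lobe: lateral surface	9	Occipital lobe
48	Middle occipital gyrus	R	20	Occipital lobe: lateral surface	10	Occipital lobe
49	Inferior occipital gyrus	L	19	Occipital lobe: lateral surface	9	Occipital lobe
50	Inferior occipital gyrus	R	20	Occipital lobe: lateral surface	10	Occipital lobe
51	Fusiform gyrus	L	21	Occipital lobe: medial and inferior surfaces	9	Occipital lobe
52	Fusiform gyrus	R	22	Occipital lobe: medial and inferior surfaces	10	Occipital lobe
53	Postcentral gyrus	L	3	Central region: postcentral gyrus	1	Central region
54	Postcentral gyrus	R	4	Central region: postcentral gyrus	2	Central region
55	Superior parietal gyrus	L	15	Parietal lobe: lateral surface	7	Parietal lobe
56	Superior parietal gyrus	R	16	Parietal lobe: lateral surface	8	Parietal lobe
57	Inferior parietal lobule	L	15	Parietal lobe: lateral surface	7	Parietal lobe
58	Inferior parietal lobule	R	16	Parietal lobe: lateral surface	8	Parietal lobe
59	Supramarginal gyrus	L	15	Parietal lobe: lateral surface	7	Parietal lobe
60	Supramarginal gyrus	R	16	Parietal lobe: lateral surface	8	Parietal lobe
61	Angular gyrus	L	15	Parietal lobe: lateral surface	7	Parietal lobe
62	Angular gyrus	R	16	Parietal lobe: lateral surface	8	Parietal lobe
63	Precuneus	L	17	Parietal lobe: medial surface	7	Parietal lobe
64	Precuneus	R	18	Parietal lobe: medial surface	8	Parietal lobe
65	Paracentral lobule	L	9	Frontal lobe: medial surface	3	Frontal lobe
66	Paracentral lobule	R	10	Frontal lobe: medial surface	4	Frontal lobe
67	Heschl gyrus	L	13	Temporal lobe: lateral surface	5	Temporal lobe
68	Heschl gyrus	R	14	Temporal lobe: lateral surface	6	Temporal lobe
69	Superior temporal gyrus	L	13	Temporal lobe: lateral surface	5	Temporal lobe
70	Superior temporal gyrus	R	14	Temporal lobe: lateral surface	6	Temporal lobe
71	Temporal pole (superior)	L	23	Limbic lobe: temporal pole (superior)	11	Limbic lobe
72	Temporal pole (superior)	R	24	Limbic lobe: temporal pole (superior)	12	Limbic lobe
73	Middle temporal gyrus	L	13	Temporal lobe: lateral surface	5	Temporal lobe
74	Middle temporal gyrus	R	14	Temporal lobe: lateral surface	6	Temporal lobe
75	Temporal pole (middle)	L	25	Limbic lobe: temporal pole (middle)	11	Limbic lobe
76	Temporal pole (middle)	R	26	Limbic lobe: temporal pole (middle)	12	Limbic lobe
77	Inferior temporal gyrus	L	13	Temporal lobe: lateral surface	5	Temporal lobe
78	Inferior temporal gyrus	R	14	Temporal lobe: lateral surface	6	Temporal lobe
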