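item_id	subgroup_id	category_id	conversion_factor
1	1	1	1.0
2	2	1	0.5
3	3	1	2.0
4	4	1	1.5
5	5	1	0.75
6	6	1	1.0
7	7	1	0.5
8	8	1	2.0
9	9	1	1.5
10	10	1	0.75
11	11	1	1.0
12	12	1	0.5
13	13	1	2.0
14	14	1	1.5
15	15	1	0.75
16	16	1	1.0
17	17	1	0.5
18	18	1	2.0
19	19	1	1.5
20	20	2	0.75
21	21	2	1.0
22	22	2	0.5
23	23	2	2.0
24	24	2	1.5
25	25	2	0.75
26	26	2	1.0
27	27	2	0.5
28	28	2	2.0
29	29	2	1.5
30	30	2	0.75
31	31	2	1.0
32	32	2	0.5
33	33	2	2.0
34	34	2	1.5
35	35	2	0.75
36	36	2	1.0
37	37	2	0.5
38	38	2	2.0
39	39	3	1.5
40	40	3	0.75
41	41	3	1.0
42	42	3	0.5
43	43	3	2.0
44	44	3	1.5
45	45	3	0.75
46	46	3	1.0
47	47	3	0.5
48	48	3	2.0
49	49	3	1.5
50	50	3	0.75
51	51	3	1.0
52	52	3	0.5
53	53	3	2.0
54	54	3	1.5
55	55	3	0.75
56	56	3	1.0
57	57	3	0.5
58	58	4	2.0
59	59	4	1.5
60	60	4	0.75
61	61	4	1.0
62	62	4	0.5
63	63	4	2.0
64	64	4	1.5
65	65	4	0.75
66	66	4	1.0
67	67	4	0.5
68	68	4	2.0
69	69	4	1.5
70	70	4	0.75
71	71	4	1.0
72	72	4	0.5
73	73	4	2.0
74	74	4	1.5
75	75	4	0.75
76	76	4	1.0
77	77	5	0.5
78	78	5	2.0
79	79	5	1.5
80	80	5	0.75
81	81	5	1.0
82	82	5	0.5
83	83	5	2.0
84	84	5	1.5
85	85	5	0.75
86	86	5	1.0
87	87	5	0.5
88	88	5	2.0
89	89	5	1.5
90	90	5	0.75
91	91	5	1.0
92	92	5	0.5
93	93	5	2.0
94	94	5	1.5
95	95	5	0.75
96	96	6	1.0
97	97	6	0.5
98	98	6	2.0
99	99	6	1.5
100	100	6	0.75
101	101	6	1.0
102	102	6	0.5
103	103	6	2.0
104	104	6	1.5
105	105	6	0.75
106	106	6	1.0
107	107	6	0.5
108	108	6	2.0
109	109	6	1.5
110	110	6	0.75
111	111	6	1.0
112	112	6	0.5
113	113	6	2.0
114	114	6	1.5
115	115	7	0.75
116	116	7	1.0
117	117	7	0.5
118	118	7	2.0
119	119	7	1.5
120	120	7	0.75
121	121	7	1.0
122	122	7	0.5
123	123	7	2.0
124	124	7	1.5
125	125	7	0.75
126	126	7	1.0
127	127	7	0.5
128	128	7	2.0
129	129	7	1.5
130	169	10	0.75
131	170	10	1.0
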