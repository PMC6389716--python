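node_index	module
1	SMN
2	SMN
3	SMN
4	SMN
5	SMN
6	SMN
7	SMN
8	SMN
9	SMN
10	SMN
11	SMN
12	SMN
13	SMN
14	SMN
15	SMN
16	SMN
17	SMN
18	SMN
19	SMN
20	SMN
21	SMN
22	SMN
23	SMN
24	SMN
25	SMN
26	SMN
27	SMN
28	SMN
29	SMN
30	SMN
31	SMN
32	SMN
33	SMN
34	SMN
35	SMN
36	CON
37	CON
38	CON
39	CON
40	CON
41	CON
42	CON
43	CON
44	CON
45	CON
46	CON
47	CON
48	CON
49	CON
50	Auditory
51	Auditory
52	Auditory
53	Auditory
54	Auditory
55	Auditory
56	Auditory
57	Auditory
58	Auditory
59	Auditory
60	Auditory
61	Auditory
62	Auditory
63	DMN
64	DMN
65	DMN
66	DMN
67	DMN
68	DMN
69	DMN
70	DMN
71	DMN
72	DMN
73	DMN
74	DMN
75	DMN
76	DMN
77	DMN
78	DMN
79	DMN
80	DMN
81	DMN
82	DMN
83	DMN
84	DMN
85	DMN
86	DMN
87	DMN
88	DMN
89	DMN
90	DMN
91	DMN
92	DMN
93	DMN
94	DMN
95	DMN
96	DMN
97	DMN
98	DMN
99	DMN
100	DMN
101	DMN
102	DMN
103	DMN
104	DMN
105	DMN
106	DMN
107	DMN
108	DMN
109	DMN
110	DMN
111	DMN
112	DMN
113	DMN
114	DMN
115	DMN
116	DMN
117	DMN
118	DMN
119	DMN
120	DMN
121	MemoryRetrieval
122	MemoryRetrieval
123	MemoryRetrieval
124	MemoryRetrieval
125	MemoryRetrieval
126	Visual
127	Visual
128	Visual
129	Visual
130	Visual
131	Visual
132	Visual
133	Visual
134	Visual
135	Visual
136	Visual
137	Visual
138	Visual
139	Visual
140	Visual
141	Visual
142	Visual
143	Visual
144	Visual
145	Visual
146	Visual
147	Visual
148	Visual
149	Visual
150	Visual
151	Visual
152	Visual
153	Visual
154	Visual
155	Visual
156	Visual
157	FPN
158	FPN
159	FPN
160	FPN
161	FPN
162	FPN
163	FPN
164	FPN
165	FPN
166	FPN
167	FPN
168	FPN
169	FPN
170	FPN
171	FPN
172	FPN
173	FPN
174	FPN
175	FPN
176	FPN
177	FPN
178	FPN
179	FPN
180	FPN
181	FPN
182	SAN
183	SAN
184	SAN
185	SAN
186	SAN
187	SAN
188	SAN
189	SAN
190	SAN
191	SAN
192	SAN
193	SAN
194	SAN
195	SAN
196	SAN
197	SAN
198	SAN
199	SAN
200	Subcortical
201	Subcortical
202	Subcortical
203	Subcortical
204	Subcortical
205	Subcortical
206	Subcortical
207	Subcortical
208	Subcortical
209	Subcortical
210	Subcortical
211	Subcortical
212	Subcortical
213	VAN
214	VAN
215	VAN
216	VAN
217	VAN
218	VAN
219	VAN
220	VAN
221	VAN
222	DAN
223	DAN
224	DAN
225	DAN
226	DAN
227	DAN
228	DAN
229	DAN
230	DAN
231	DAN
232	DAN
233	Cerebellum
234	Cerebellum
235	Cerebellum
236	Cerebellum
237	Uncertain
238	Uncertain
239	Uncertain
240	Uncertain
241	Uncertain
242	Uncertain
243	Uncertain
244	Uncertain
245	Uncertain
246	Uncertain
247	Uncertain
248	Uncertain
249	Uncertain
250	Uncertain
251	Uncertain
252	Uncertain
253	Uncertain
254	Uncertain
255	Uncertain
256	Uncertain
257	Uncertain
258	Uncertain
259	Uncertain
260	Uncertain
261	Uncertain
262	Uncertain
263	Uncertain
264	Uncertain
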