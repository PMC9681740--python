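code,canonical
1,1
2,1
3,3
4,3
5,5
6,5
7,7
8,7
9,9
10,9
11,11
12,11
13,13
14,13
15,15
16,15
17,17
18,17
19,19
20,19
21,21
22,21
23,23
24,23
25,25
26,25
27,27
28,27
29,29
30,29
31,31
32,31
33,33
34,33
35,35
36,35
37,37
38,37
39,39
40,39
41,41
42,41
43,43
44,43
45,45
46,45
47,47
48,47
49,49
50,49
51,51
52,51
53,53
54,53
55,55
56,55
57,57
58,57
59,59
60,59
61,61
62,61
63,63
64,63
65,65
66,65
67,67
68,67
69,69
70,69
71,71
72,71
73,73
74,73
75,75
76,75
77,77
78,77
79,79
80,79
81,81
82,81
83,83
84,83
85,85
86,85
87,87
88,87
89,89
90,89
91,91
92,91
93,93
94,93
95,95
96,95
97,97
98,97
99,99
100,99
101,101
102,101
103,103
104,103
105,105
106,105
107,107
108,107
109,109
110,109
111,111
112,111
113,113
114,113
115,115
116,115
117,117
118,117
119,119
120,119
121,121
122,121
123,123
124,123
125,125
126,125
127,127
128,127
129,129
130,129
131,131
132,131
133,133
134,133
135,135
136,135
137,137
138,137
139,139
140,139
141,141
142,141
143,143
144,143
145,145
146,145
147,147
148,147
149,149
150,149
155,155
156,155
157,157
158,157
159,159
160,159
161,161
162,161
163,163
164,163
165,165
166,165
167,167
168,167
169,169
170,169
171,171
172,171
173,173
174,173
175,175
176,175
177,177
178,177
179,179
180,179
181,181
182,181
185,185
186,185
187,187
188,187
189,189
190,189
191,191
192,191
193,193
194,193
195,195
196,195
197,197
198,197
199,199
200,199
201,201
202,201
203,203
204,203
205,205
206,205
207,207
208,207
209,209
210,209
211,211
212,211
213,213
214,213
215,215
216,215
218,218
219,218
220,220
221,220
222,222
223,222
224,224
225,224
227,227
228,227
229,229
230,229
233,233
234,233
235,235
236,235
238,238
239,238
240,240
241,240
242,242
243,242
244,244
245,244
246,246
247,246
248,248
249,248
250,250
251,250
252,252
253,252
254,254
255,254
256,256
257,256
258,258
259,258
260,260
261,260
262,262
263,262
264,264
265,264
266,266
267,266
268,268
269,268
270,270
271,270
272,272
273,272
274,274
275,274
276,276
277,276
278,278
279,278
280,280
281,280
282,282
283,282
284,284
285,284
286,286
287,286
288,288
289,288
290,290
291,290
292,292
293,292
294,294
295,294
296,296
297,296
298,298
299,298
300,300
301,300
302,302
303,302
306,306
307,306
308,308
309,308
313,313
314,313
315,315
316,315
317,317
318,317
321,321
322,321
323,323
324,323
325,325
326,325
327,327
328,327
329,329
330,329
390,390
391,390
392,390
393,390
436,436
437,436
438,436
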