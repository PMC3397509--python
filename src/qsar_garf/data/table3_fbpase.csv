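compound_no,observed,garf_pred,rf_pred,is_test,source
1,7.00,6.62,6.70,0,ref29
2,6.40,6.20,6.25,1,ref29
3,5.92,5.99,6.05,0,ref29
4,6.66,6.63,6.61,0,ref29
5,6.30,6.05,6.27,1,ref29
6,6.74,6.61,6.64,0,ref29
7,7.10,6.85,6.89,0,ref29
8,6.05,6.23,6.16,0,ref29
9,5.70,5.65,5.73,0,ref29
10,7.60,7.38,7.20,1,ref29
11,6.00,5.95,6.08,0,ref29
12,5.00,5.69,5.66,0,ref29
13,5.56,5.75,6.03,0,ref29
14,6.30,6.38,6.39,1,ref29
15,4.87,5.33,5.40,0,ref29
16,5.10,5.93,5.78,1,ref29
17,5.30,5.40,5.55,0,ref29
18,6.35,6.38,6.42,0,ref29
19,6.92,6.84,6.80,0,ref29
20,6.30,6.73,6.55,0,ref29
21,7.52,7.29,7.13,1,ref29
22,7.55,7.04,7.01,1,ref29
23,7.24,6.99,7.14,0,ref29
24,7.92,7.58,7.51,0,ref29
25,7.72,7.61,7.54,0,ref29
26,7.68,7.67,7.58,1,ref29
27,8.00,7.80,7.83,0,ref29
28,7.70,7.62,7.53,0,ref29
29,7.74,7.36,7.44,0,ref29
30,7.23,7.18,7.08,0,ref29
31,6.82,6.85,6.82,0,ref29
32,6.25,6.16,6.45,1,ref29
33,7.15,7.03,6.97,0,ref29
34,7.30,6.99,6.88,1,ref29
35,7.00,6.87,6.36,1,ref29
36,7.80,7.09,7.29,0,ref29
37,7.48,7.32,7.24,0,ref29
38,7.80,7.21,7.03,1,ref29
39,7.62,7.50,7.46,0,ref29
40,7.62,7.52,7.53,0,ref29
41,6.52,6.70,6.58,1,ref29
42,5.77,5.94,6.22,0,ref29
43,7.85,7.55,7.48,0,ref29
44,7.82,7.25,7.43,0,ref29
45,6.07,6.56,6.45,0,ref29
46,7.85,7.68,7.64,1,ref29
47,7.37,7.51,7.52,1,ref29
48,7.68,7.60,7.62,0,ref29
49,7.66,7.61,7.64,0,ref29
50,7.68,7.41,7.40,1,ref29
51,7.06,7.21,7.10,0,ref29
52,7.85,7.48,7.36,1,ref29
53,7.80,7.71,7.68,0,ref29
54,7.89,7.76,7.75,0,ref29
55,7.49,7.45,7.48,0,ref29
56,7.39,7.30,7.00,0,ref29
57,7.47,7.31,7.23,1,ref29
58,7.92,7.66,7.61,0,ref29
59,7.40,7.12,7.22,0,ref29
60,7.36,7.17,7.20,1,ref29
61,5.00,5.41,5.78,0,ref29
62,7.30,6.90,6.92,0,ref29
63,6.02,6.42,6.69,1,ref29
64,5.70,5.74,5.94,0,ref29
65,5.89,6.06,6.01,0,ref29
66,6.87,6.71,6.39,1,ref29
67,6.68,7.05,6.89,1,ref29
68,7.10,7.42,7.27,1,ref29
69,6.92,6.38,6.13,1,ref30
70,5.00,5.60,5.43,0,ref30
71,6.85,6.70,6.51,0,ref30
72,6.77,6.64,6.54,0,ref30
73,6.68,6.54,6.35,1,ref30
74,6.49,6.24,6.29,0,ref30
75,6.80,6.78,6.80,0,ref30
76,6.05,6.23,6.12,0,ref30
77,6.59,6.47,6.59,0,ref30
78,7.15,6.97,6.91,0,ref30
79,6.96,7.01,7.02,0,ref30
80,6.92,6.64,7.05,1,ref30
81,5.40,5.79,6.08,0,ref30
82,7.17,7.06,6.70,0,ref30
83,7.42,7.10,6.85,1,ref30
84,7.40,7.13,7.14,0,ref30
85,7.07,6.95,6.91,0,ref30
86,7.52,7.23,7.20,0,ref30
87,6.07,6.10,6.22,0,ref30
88,6.22,6.24,6.14,0,ref30
89,5.00,5.48,5.43,0,ref30
90,5.72,5.87,5.80,1,ref30
91,5.68,5.61,5.54,0,ref30
92,5.66,5.79,5.78,1,ref30
93,5.37,5.55,5.62,0,ref30
94,6.02,6.09,5.94,0,ref30
95,5.00,5.43,5.68,1,ref30
96,5.17,5.49,5.54,0,ref30
97,5.15,5.50,5.43,0,ref30
98,6.38,6.19,5.72,1,ref30
99,6.42,6.39,6.17,0,ref30
100,6.55,6.46,6.08,1,ref30
101,6.24,6.36,6.19,1,ref30
102,6.60,6.32,5.98,1,ref30
103,6.46,6.30,6.10,1,ref30
104,5.00,5.45,5.54,0,ref30
105,5.00,5.35,5.45,0,ref30
106,5.30,5.55,5.47,0,ref31
107,5.26,5.58,5.56,0,ref31
108,7.38,6.95,6.87,0,ref31
109,4.00,4.36,4.62,1,ref32
110,3.85,4.27,4.56,1,ref32
111,4.00,4.27,4.44,0,ref32
112,4.04,4.20,4.26,0,ref32
113,4.00,4.14,4.20,1,ref32
114,4.46,4.35,4.42,0,ref32
115,4.00,4.19,4.50,1,ref32
116,4.00,4.04,4.16,0,ref32
117,4.00,4.19,4.28,1,ref32
118,3.84,4.03,4.29,0,ref32
119,4.64,4.09,4.38,1,ref32
120,5.30,4.95,4.95,0,ref32
121,4.32,4.55,4.71,0,ref32
122,4.40,4.13,4.21,1,ref32
123,3.82,4.43,4.50,0,ref32
124,3.60,4.11,4.17,0,ref32
125,4.30,4.46,4.41,0,ref32
126,4.30,4.61,4.59,0,ref32
127,4.15,4.31,4.47,0,ref32
128,5.85,5.54,5.54,0,ref32
129,5.48,5.22,5.19,0,ref32
130,5.82,5.70,5.78,0,ref32
131,5.70,5.69,5.76,0,ref32
132,5.74,5.65,5.76,0,ref32
133,5.82,5.81,5.82,0,ref32
134,6.10,5.87,5.87,0,ref32
135,6.15,5.52,5.42,1,ref32
136,4.55,4.95,4.99,0,ref32
137,5.35,5.52,5.40,1,ref32
138,6.05,5.83,5.91,0,ref32
139,5.80,5.66,5.67,1,ref32
140,5.30,5.72,5.74,1,ref32
141,5.26,5.27,5.27,0,ref32
142,5.96,5.54,5.42,1,ref32
143,4.89,5.56,5.42,1,ref32
144,5.22,5.49,5.70,1,ref33
145,5.65,5.80,5.88,0,ref33
146,5.96,6.00,6.03,0,ref33
147,5.82,5.91,6.00,1,ref33
148,6.10,6.03,6.02,0,ref33
149,6.10,6.04,6.01,0,ref33
150,5.82,5.87,5.81,0,ref33
151,5.60,5.64,5.63,0,ref33
152,5.49,5.57,5.64,0,ref33
153,6.00,5.94,5.85,0,ref33
154,5.30,5.72,5.70,1,ref33
155,5.02,5.26,5.34,0,ref33
156,5.15,5.50,5.51,0,ref33
157,5.60,5.63,5.59,0,ref33
158,5.38,5.74,5.68,1,ref33
159,5.73,5.87,5.75,1,ref33
160,5.40,6.02,6.08,1,ref33
161,5.60,5.86,5.87,1,ref33
162,5.52,5.69,5.66,0,ref33
163,6.15,6.41,6.25,1,ref33
164,6.30,6.23,6.24,0,ref33
165,6.70,6.52,6.56,0,ref33
166,6.05,6.19,6.11,0,ref33
167,6.40,6.32,6.29,0,ref33
168,6.40,6.21,6.14,1,ref33
169,7.00,6.56,6.47,1,ref33
170,6.82,6.83,6.57,1,ref33
171,6.07,6.42,6.38,0,ref33
172,7.26,6.54,6.53,1,ref33
173,6.00,6.09,6.03,0,ref33
174,6.35,6.34,6.30,0,ref33
175,7.00,6.77,6.67,1,ref33
176,6.89,6.75,6.67,0,ref33
177,6.65,6.66,6.59,0,ref33
178,5.00,5.53,5.60,0,ref33
179,6.55,6.90,6.94,1,ref33
180,7.22,7.08,7.10,0,ref33
181,7.05,6.79,6.83,1,ref33
182,6.74,6.74,6.75,0,ref33
183,7.05,6.94,6.81,0,ref33
184,7.26,7.07,7.06,0,ref33
185,7.00,6.99,7.02,0,ref33
186,6.68,6.70,6.67,0,ref33
187,7.00,6.92,6.99,0,ref33
188,7.10,6.97,7.05,0,ref33
189,7.26,6.72,6.73,0,ref33
190,7.15,6.74,6.78,1,ref33
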