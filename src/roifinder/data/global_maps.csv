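map_id,roi_detected
1,True
2,True
3,True
4,True
5,True
6,True
7,True
8,True
9,True
10,True
11,True
12,True
13,True
14,True
15,True
16,True
17,True
18,True
19,True
20,True
21,True
22,True
23,True
24,True
25,True
26,True
27,True
28,True
29,True
30,True
31,True
32,True
33,True
34,True
35,True
36,True
37,True
38,True
39,True
40,True
41,True
42,True
43,True
44,True
45,True
46,True
47,True
48,True
49,True
50,True
51,True
52,True
53,True
54,True
55,True
56,True
57,True
58,True
59,True
60,True
61,True
62,True
63,True
64,True
65,True
66,True
67,True
68,True
69,True
70,True
71,True
72,True
73,True
74,True
75,True
76,True
77,True
78,True
79,True
80,True
81,True
82,True
83,True
84,True
85,True
86,True
87,True
88,True
89,True
90,True
91,True
92,True
93,True
94,True
95,True
96,True
97,True
98,True
99,True
100,True
101,True
102,True
103,True
104,True
105,True
106,True
107,True
108,True
109,True
110,True
111,True
112,True
113,True
114,True
115,True
116,True
117,True
118,True
119,True
120,True
121,True
122,False
123,False
124,False
125,False
126,False
127,False
128,False
129,False
130,False
131,False
132,False
133,False
134,False
135,False
136,False
137,False
138,False
139,False
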