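# Per-identity image counts after similarity filtering (the study's
# 60-sheep dataset distribution); used to reconstruct the dataset-
# arithmetic conditions. version: 1
class_id,filtered_count
0,134
1,73
2,80
3,78
4,78
5,76
6,68
7,85
8,109
9,87
10,117
11,62
12,100
13,62
14,110
15,120
16,107
17,67
18,112
19,97
20,79
21,117
22,68
23,90
24,86
25,101
26,76
27,132
28,122
29,90
30,109
31,137
32,98
33,148
34,101
35,119
36,117
37,120
38,156
39,122
40,97
41,147
42,120
43,108
44,120
45,164
46,98
47,101
48,127
49,156
50,126
51,106
52,168
53,131
54,129
55,119
56,55
57,113
58,114
59,109
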