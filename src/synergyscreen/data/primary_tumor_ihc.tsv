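sample	diagnosis	score	response	debulking	age	stage	ca125
1	Focal adenocarcinoma	6	CR	O	57	IIIC	541
2	Papillary serous adenocarcinoma	1	CR	O	84	IIIC	7350
3	Adenocarcinoma	2	CR	O	53	IIIC
4	Papillary serous adenocarcinoma	4	CR	O	61	IIIC
5	Papillary serous adenocarcinoma	6	CR	O	57	IIIC
6	Papillary serous adenocarcinoma	1	CR	O	55	IV
7	Papillary serous adenocarcinoma	2	CR	O	49	IIIC	305
8	Papillary serous adenocarcinoma	1	CR	O	65	IIIC
9	Papillary serous adenocarcinoma	4	CR	O	60	IIIC	925
10	Papillary serous adenocarcinoma	2	CR	O	51	IIIB
11	Papillary serous adenocarcinoma	4	CR	O	56	IIIC	316
12	Papillary serous adenocarcinoma	2	CR	O	66	IIIC	224
13	Papillary serous adenocarcinoma	2	CR	S	56	IIIC
14	Papillary serous adenocarcinoma	4	CR	O	73	IIIC
15	Papillary serous adenocarcinoma	1	CR	O	62	IIIC	1717
16	Papillary serous adenocarcinoma	2	CR	O	78	IIIC
17	Papillary serous adenocarcinoma	6	CR	O	43	IIIC	64
18	Papillary serous adenocarcinoma	1	CR	O	45	IIIC
19	Papillary serous adenocarcinoma	1	CR	S	74	IIIC	1800
20	Papillary serous adenocarcinoma	2	CR	O	76	IIIC
21	Papillary serous adenocarcinoma	2	IR	S	79	IV
22	Papillary serous adenocarcinoma	2	IR	S	71	IV	1636
23	Papillary serous adenocarcinoma	2	CR	O	56	IIIC
24	Papillary serous adenocarcinoma	1	CR	O	81	IIIC
25	Papillary serous adenocarcinoma	2	CR	O	56	IIIC	260
26	papillary serous adenocarcinoma	3	CR	O	35	IV	47
27	Papillary serous adenocarcinoma	2	CR	O	53	IIIA
28	Papillary serous adenocarcinoma	1	CR	S	77	IV	>600
29	Papillary serous adenocarcinoma	2	CR	O	65	IIIC	1118
30	Papillary serous adenocarcinoma	1	CR	S	47	IIIC	712
31	Papillary serous adenocarcinoma	2	CR	S	76	IIIC	1848
32	Papillary serous adenocarcinoma	2	CR	O	70	IIIC
33	Papillary serous adenocarcinoma	3	CR	S	57	IIIC	266
34	Adenocarcinoma metastatic	2	CR	O	57	IIIC	175
35	Papillary serous adenocarcinoma	1	CR	O	65	IV	404
36	Papillary serous adenocarcinoma	2	CR	O	76	IV
37	Papillary serous adenocarcinoma	1	CR	O	66	IIIC
38	Papillary serous adenocarcinoma	1	CR	O	68	IIIC
39	Papillary serous adenocarcinoma	3	IR	O	73	IIIC
40	Papillary serous adenocarcinoma	2	CR	O	63	IV
41	Papillary serous adenocarcinoma	2	IR	S	63	IIIC
42	Papillary serous adenocarcinoma	2	IR	O	47	IIIC
43	Papillary serous adenocarcinoma	2	CR	O	42	IIIC	110
44	Papillary serous adenocarcinoma	1	CR	O	74	IIIC	4557
45	Papillary serous adenocarcinoma	2	CR	S	64	IIIC
46	Papillary serous adenocarcinoma	2	IR	S	64	IIIC	456
47	Papillary serous adenocarcinoma	1	IR	O	71	IIIC
48	Papillary serous adenocarcinoma	6	IR	O	69	IIIC
49	Papillary serous adenocarcinoma	3	CR	O	49	IIIC
50	Papillary serous adenocarcinoma	2	CR	O	62	IV
51	Papillary serous adenocarcinoma	2	IR
52	Focal adenocarcinoma	3	CR	S	88	IIIC
53	Serous adenocarcinoma	1	IR	O	74	IIIC	101
54	Papillary serous adenocarcinoma	2	IR	O	71	IIIC
55	Papillary serous adenocarcinoma	4	IR	O	69	IIIC	1606
56	Papillary serous adenocarcinoma	1	IR	O	52	IIIC
57	Papillary serous adenocarcinoma	2	CR	O	67	IIIC
58	Papillary serous adenocarcinoma	1	CR	O	66	IIIC	824
59	Papillary Serous adenocarcinoma	2	IR	O	52	IIIC
60	Papillary serous adenocarcinoma	1	CR	S	73	IIIC	2354
61	Papillary serous adenocarcinoma	0	CR	O	75	IIIC
62	Papillary serous adenocarcinoma	2	IR	O	65	IIIC
63	Focal cellular atypia	n/a	CR	O	74	IIIC
64	Papillary serous adenocarcinoma	2	IR	O	79	IIIC	417
65	Papillary serous adenocarcinoma	1	CR	O	73	IIIC	180
66	Papillary serous adenocarcinoma	2	IR	O	53	IV	96
67	Papillary serous adenocarcinoma	1	CR	O	60	IIIC
68	Papillary serous adenocarcinoma	2	CR
69	Papillary serous adenocarcinoma	2	IR	S	53	IIIC
70	Papillary serous adenocarcinoma	1	IR	O	41	IIIC	2800
71	Papillary serous adenocarcinoma	1	CR	O	80	IIIC
72	Papillary serous adenocarcinoma	2	CR	O	42	IIIA
73	Papillary serous adenocarcinoma	2	IR	S	66	IIIC	90
74	Papillary serous adenocarcinoma	1	CR	S	60	IIIC	750
75	Papillary serous adenocarcinoma	4	CR	O	77	IIIC	9814
76	Papillary serous adenocarcinoma	0	CR	O	72	III
77	Papillary serous adenocarcinoma	1	IR	O	66	IIIC
78	Papillary serous adenocarcinoma	0	CR	O	54	III
79	Papillary serous adenocarcinoma	3	CR	O	38	IIIC
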