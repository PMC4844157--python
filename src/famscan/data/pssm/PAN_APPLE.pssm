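# famscan PSSM v1
id	PAN_APPLE
length	36
min_score	108
alphabet	ACDEFGHIKLMNPQRSTVWY
1	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
3	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
4	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5
6	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
7	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
8	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
9	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2
10	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
11	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
12	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
13	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
14	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
15	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2
16	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
17	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
18	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
19	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
20	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2
21	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2
22	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
23	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2
24	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2
25	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2
26	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
27	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2
28	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2
29	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
30	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
31	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
32	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
33	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2
34	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
35	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
36	-2	-2	-2	-2	-2	5	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2	-2
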