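# taxon: antongilensis
# annotation NOR: close to the centromeres of pair 2
# transcribed from the published chromosome morphometric table, Blaesodactylus antongilensis column (2n = 40)
# pair 1 centromeric index 25.0 sits exactly on the subtelocentric/submetacentric transition
rank	rl_mean	rl_sd	ci_mean	ci_sd	morph
1	9.6	0.7	25.0	4.0	st/sm
2	8.7	1.1	NA	NA	t
3	7.4	0.4	NA	NA	t
4	7.3	0.5	NA	NA	t
5	7.0	0.7	NA	NA	t
6	6.7	0.6	38.4	3.5	m
7	6.2	0.9	NA	NA	t
8	5.6	0.8	NA	NA	t
9	5.0	0.6	NA	NA	t
10	4.9	0.5	NA	NA	t
11	4.8	0.8	NA	NA	t
12	4.6	0.4	NA	NA	t
13	4.0	0.6	NA	NA	t
14	3.3	1.0	NA	NA	t
15	3.2	0.8	NA	NA	t
16	2.8	0.9	NA	NA	t
17	2.6	0.7	NA	NA	t
18	2.3	0.6	NA	NA	t
19	2.0	0.5	NA	NA	t
20	2.0	0.8	NA	NA	t
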