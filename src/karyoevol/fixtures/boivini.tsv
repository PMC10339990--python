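# taxon: boivini
# annotation NOR: close to the centromeres of pair 1
# transcribed from the published chromosome morphometric table, Blaesodactylus boivini column (2n = 42, all telocentric)
rank	rl_mean	rl_sd	ci_mean	ci_sd	morph
1	9.7	0.6	NA	NA	t
2	8.2	0.4	NA	NA	t
3	7.4	1.2	NA	NA	t
4	6.6	0.9	NA	NA	t
5	5.8	0.7	NA	NA	t
6	5.8	1.0	NA	NA	t
7	5.7	0.5	NA	NA	t
8	5.6	0.4	NA	NA	t
9	5.6	0.6	NA	NA	t
10	5.6	0.6	NA	NA	t
11	4.6	0.5	NA	NA	t
12	3.9	0.5	NA	NA	t
13	3.3	0.4	NA	NA	t
14	3.3	0.8	NA	NA	t
15	3.2	0.6	NA	NA	t
16	3.2	0.7	NA	NA	t
17	2.9	0.5	NA	NA	t
18	2.8	0.4	NA	NA	t
19	2.4	0.4	NA	NA	t
20	2.3	0.3	NA	NA	t
21	1.9	0.5	NA	NA	t
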