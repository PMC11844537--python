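tf	rank_eigenvector	rank_degree_out	rank_betweenness	total_score
Npas2	0	0	12	12
Nr4a1	4	4	5	13
Foxo3	2	17	0	19
Ppargc1a	6	3	10	19
Smad3	15	1	4	20
Nfia	1	7	15	23
Hlx	19	2	3	24
Mecom	3	5	17	25
Ppara	9	9	8	26
Hivep1	5	10	14	29
Ebf1	13	6	11	30
Fosl2	8	16	7	31
Cebpb	11	11	9	31
Nfib	16	14	2	32
Irf4	18	15	1	34
Bcl6	12	8	16	36
Nr4a2	14	19	6	39
Pbx1	10	13	18	41
Pparg	17	12	13	42
Thra	7	18	19	44
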