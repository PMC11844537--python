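tf	rank_eigenvector	rank_degree_out	rank_betweenness	total_score
Hlx	3	1	4	8
Bhlhe40	2	4	3	9
Ezh2	0	0	12	12
Ybx2	6	2	10	18
Hivep1	5	13	5	23
Tead1	13	5	6	24
Ppargc1a	8	10	7	25
Ppara	4	11	13	28
Ar	10	17	2	29
Hivep2	9	3	17	29
Tcf7l1	1	14	14	29
Stat5a	12	18	1	31
Ebf1	15	8	8	31
Trim28	11	6	18	35
Cebpb	14	12	9	35
Nr2c2	16	9	11	36
Mecom	7	15	16	38
Nfia	19	19	0	38
Nr4a1	17	7	15	39
Nr4a2	18	16	19	53
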