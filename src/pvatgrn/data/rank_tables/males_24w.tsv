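tf	rank_eigenvector	rank_degree_out	rank_betweenness	total_score
Cebpb	3	0	2	5
Nr4a3	4	2	6	12
Nr4a2	2	1	11	14
Hivep2	0	7	8	15
Irf4	6	4	7	17
Mecom	15	3	5	23
Bach2	9	14	1	24
Epas1	10	11	4	25
Hivep1	1	16	9	26
Ppard	8	19	0	27
Atf3	5	5	19	29
Npas2	11	10	10	31
Ebf1	7	12	13	32
Ppargc1a	13	17	3	33
Mitf	12	6	17	35
Nr4a1	16	8	16	40
Ppara	19	9	12	40
Nfia	17	13	14	44
Tcf7l1	14	15	18	47
Rxrg	18	18	15	51
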