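tf	rank_eigenvector	rank_degree_out	rank_betweenness	total_score
Nr4a1	0	1	2	3
Epas1	3	2	0	5
Nr4a2	1	4	1	6
Thra	6	5	6	17
Mecom	2	3	14	19
Irf4	10	9	4	23
Nfib	4	17	3	24
Meox2	9	0	19	28
Cebpb	5	8	17	30
Rxra	7	7	16	30
Nr1h2	19	6	5	30
Ppara	8	14	10	32
Srebf1	13	11	8	32
Hivep2	14	12	9	35
Ppargc1a	16	10	11	37
Bhlhe40	17	13	7	37
Ebf1	15	15	12	42
Pparg	11	19	13	43
Mafg	12	18	18	48
Rxrg	18	16	15	49
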