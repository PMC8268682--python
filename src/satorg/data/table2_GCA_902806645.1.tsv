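family_id	LG1	LG2	LG3	LG4	LG5	LG6	LG7	LG8	LG9	LG10	chromosomes_occupied	monomers_on_chromosomes	monomers_on_scaffolds	mean_monomers_per_chromosome
CgiSat01	1	1	1	1	1	1	1	1	1	1	10	28120	3946	2812
CgiSat02	1	1	1	1	1	1	1	1	1	1	10	6499	1249	650
CgiSat03	1	1	1	1	1	1	1	1	1	1	10	2502	411	250
CgiSat04	1	1	1	1	1	1	1	1	1	1	10	223	32	22
CgiSat05	1	1	1	1	1	1	1	1	1	1	10	1811	312	181
CgiSat06	1	1	1	1	1	1	1	1	1	1	10	1628	202	163
CgiSat07	1	1	1	0	1	1	1	1	1	1	9	55	11	6
CgiSat08	1	1	1	1	1	1	1	1	1	1	10	5171	1030	517
CgiSat09	1	1	1	1	1	1	1	1	1	1	10	4411	406	441
CgiSat10	1	1	1	1	1	1	1	1	1	1	10	1082	328	108
CgiSat11	0	1	0	0	1	0	1	0	0	0	3	83	50	28
CgiSat12	0	1	1	0	1	1	0	1	1	0	6	244	21	41
CgiSat13	0	1	1	1	1	1	1	1	1	1	9	39	2	4
CgiSat14	1	1	1	1	1	1	1	1	1	1	10	441	119	44
CgiSat15	1	1	1	1	1	1	1	1	1	1	10	1768	163	177
CgiSat16	0	1	1	1	1	1	1	1	1	1	9	66	1	7
CgiSat17	1	1	1	1	1	1	1	1	1	1	10	1619	309	162
CgiSat18	1	1	1	1	1	1	1	1	1	1	10	363	25	36
CgiSat19	1	1	1	1	1	1	1	1	1	1	10	947	352	95
CgiSat20	0	1	1	0	1	1	1	1	1	0	7	148	54	21
CgiSat21	1	1	1	1	1	1	1	1	1	1	10	542	109	54
CgiSat22	0	0	0	1	0	0	0	0	0	0	1	45	0	45
CgiSat23	1	1	1	1	1	1	1	1	1	0	9	78	14	9
CgiSat24	1	1	1	1	1	1	1	1	1	1	10	2740	128	274
CgiSat25	1	1	1	1	1	1	1	1	1	1	10	2468	67	247
CgiSat26	0	0	0	0	0	0	0	1	0	0	1	13	0	13
CgiSat27	0	1	1	1	1	0	1	1	1	0	7	2030	57	290
CgiSat28	1	1	1	1	1	1	1	1	1	1	10	487	167	49
CgiSat29	1	1	1	1	1	1	1	1	1	1	10	277	19	28
CgiSat30	0	0	0	1	0	1	0	0	0	0	2	2	1	1
CgiSat31	1	0	0	0	0	0	0	0	0	0	1	52	0	52
CgiSat32	0	1	1	0	1	1	0	0	0	0	4	147	0	37
CgiSat33	0	1	1	1	1	1	1	1	1	1	9	3191	254	355
CgiSat34	0	1	0	0	0	0	0	1	1	1	4	12	2	3
CgiSat35	0	1	0	0	1	1	0	0	0	1	4	6	0	2
CgiSat36	1	0	0	0	0	0	0	0	0	0	1	2	57	2
CgiSat37	1	1	1	1	1	1	1	1	1	1	10	6367	516	637
CgiSat38	1	1	0	1	0	1	0	1	0	0	5	6	0	1
CgiSat39	1	1	1	1	1	1	1	1	1	1	10	1617	64	162
CgiSat40	1	1	1	1	1	1	1	1	1	1	10	402	31	40
CgiSat41	0	1	0	0	0	0	0	0	0	0	1	11	0	11
CgiSat42	1	1	1	0	1	1	1	1	0	0	7	124	31	18
CgiSat43	1	1	1	1	1	1	1	1	1	1	10	3145	380	315
CgiSat44	1	1	1	1	1	1	1	1	1	1	10	54	2	5
CgiSat45	0	1	0	0	0	0	0	0	0	0	1	1	11	1
CgiSat46	1	0	0	0	1	0	0	0	0	1	3	25	0	8
CgiSat47	1	1	1	0	1	1	0	1	1	0	7	251	79	36
CgiSat48	0	0	1	1	1	1	1	1	0	1	7	20	4	3
CgiSat49	1	1	1	1	1	1	1	1	1	1	10	77	4	8
CgiSat50	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CgiSat51	0	0	0	1	0	1	0	0	0	0	2	122	0	61
CgiSat52	1	0	0	0	0	0	0	0	0	0	1	17	0	17
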