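family_id	chr1	chr2	chr3	chr4	chr5	chr6	chr7	chr8	chr9	chr10	chromosomes_occupied	monomers_on_chromosomes	mean_monomers_per_chromosome
CgiSat01	1	1	1	1	1	1	1	1	1	1	10	28486	2849
CgiSat02	1	1	1	1	1	1	1	1	1	1	10	5563	556
CgiSat03	1	1	1	1	1	1	1	1	1	1	10	2116	212
CgiSat04	1	1	1	1	1	1	1	1	1	1	10	198	20
CgiSat05	1	1	1	1	1	1	1	1	1	1	10	1553	155
CgiSat06	1	1	1	1	1	1	1	1	1	1	10	1574	157
CgiSat07	1	1	1	1	1	1	1	1	1	1	10	48	5
CgiSat08	1	1	1	1	1	1	1	1	1	1	10	4949	495
CgiSat09	1	1	1	1	1	1	1	1	1	1	10	4609	461
CgiSat10	1	1	1	1	1	1	1	1	1	1	10	1463	146
CgiSat11	1	0	1	1	1	0	1	0	0	0	5	150	30
CgiSat12	1	1	1	1	1	0	1	1	0	1	8	672	84
CgiSat13	1	1	0	1	1	0	1	1	1	0	7	39	6
CgiSat14	1	1	1	1	1	1	1	1	1	1	10	257	26
CgiSat15	1	1	1	1	1	1	1	1	1	1	10	1897	190
CgiSat16	1	1	1	1	0	1	0	0	1	0	6	34	6
CgiSat17	1	1	1	1	1	1	1	1	1	1	10	1153	115
CgiSat18	1	1	1	1	1	1	1	1	1	1	10	372	37
CgiSat19	1	1	1	1	1	1	1	1	1	1	10	1304	130
CgiSat20	1	0	0	0	1	1	1	1	0	0	5	245	49
CgiSat21	1	1	1	1	1	1	1	1	1	1	10	505	51
CgiSat22	0	0	0	0	0	0	0	1	0	0	1	31	31
CgiSat23	1	1	1	1	1	1	1	1	1	1	10	148	15
CgiSat24	1	1	1	1	1	1	1	1	1	1	10	2829	283
CgiSat25	1	1	1	1	1	1	1	1	1	1	10	2983	298
CgiSat26	0	0	0	1	0	0	0	0	0	0	1	15	15
CgiSat27	1	0	1	1	1	0	1	1	0	1	7	1554	222
CgiSat28	1	1	1	1	1	1	1	1	1	1	10	548	55
CgiSat29	1	1	1	1	1	1	1	1	1	1	10	267	27
CgiSat30	0	0	0	0	1	0	0	1	0	0	2	4	2
CgiSat31	0	0	0	0	0	0	1	0	0	0	1	61	61
CgiSat32	1	0	0	0	0	0	1	0	0	0	2	75	38
CgiSat33	0	1	0	1	1	1	1	1	1	1	8	2789	349
CgiSat34	1	1	0	1	1	1	1	1	1	1	9	43	5
CgiSat35	0	0	1	0	0	0	1	0	0	0	2	4	2
CgiSat36	0	0	0	0	1	1	1	0	0	1	4	96	24
CgiSat37	1	1	1	1	1	1	1	1	1	1	10	6242	624
CgiSat38	1	0	1	0	0	1	0	1	1	0	5	10	2
CgiSat39	1	1	1	1	1	1	1	1	1	1	10	1235	124
CgiSat40	1	1	1	1	1	1	1	1	1	1	10	402	40
CgiSat41	1	0	0	0	0	0	0	0	0	0	1	7	7
CgiSat42	1	0	1	1	1	0	1	0	0	0	5	104	21
CgiSat43	1	1	1	1	1	1	1	1	1	1	10	3416	342
CgiSat44	1	1	1	1	1	1	1	1	1	1	10	80	8
CgiSat45	1	0	0	0	0	0	0	0	0	0	1	4	4
CgiSat46	0	1	0	1	1	1	0	1	1	0	6	359	60
CgiSat47	1	0	1	1	1	1	1	1	1	1	9	340	38
CgiSat48	1	1	1	1	0	1	0	0	0	1	6	10	2
CgiSat49	1	1	1	1	1	1	1	1	1	1	10	79	8
CgiSat50	0	0	0	0	0	0	0	0	0	0	0	0	0
CgiSat51	0	1	0	0	0	0	0	1	0	0	2	87	44
CgiSat52	0	0	0	0	0	0	1	0	0	0	1	6	6
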