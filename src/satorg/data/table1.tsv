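family_id	variant_id	monomer_length	genome_pct	satellitome_pct	at_pct	repbase_class
CgiSat01	CgiSat01a	164	0.72	11.29	59.8	DNA/Helitron
CgiSat01	CgiSat01b	166	0.57	9.04	57.2	DNA/Helitron
CgiSat02	CgiSat02	437	0.44	6.91	65.7	DNA/Helitron
CgiSat03	CgiSat03	437	0.38	6.0	67.5	DNA/Helitron
CgiSat04	CgiSat04	2077	0.34	5.32	67.3	DNA/Helitron
CgiSat05	CgiSat05	811	0.38	6.0	67.6	DNA/Helitron
CgiSat06	CgiSat06	622	0.33	5.13	67.4	DNA/Helitron
CgiSat07	CgiSat07	2091	0.21	3.24	67.0	DNA/Helitron
CgiSat08	CgiSat08	166	0.19	2.96	67.5	DNA/Helitron
CgiSat09	CgiSat09	166	0.15	2.33	63.3	DNA/Helitron
CgiSat10	CgiSat10	433	0.14	2.26	63.0	DNA/Helitron
CgiSat11	CgiSat11	892	0.14	2.21	64.6	LTR/BEL
CgiSat12	CgiSat12	446	0.11	1.78	64.8	
CgiSat13	CgiSat13	2414	0.11	1.74	67.4	DNA/Kolobok
CgiSat14	CgiSat14	1144	0.11	1.74	68.9	DNA/Helitron
CgiSat15	CgiSat15	177	0.08	1.32	68.9	
CgiSat16	CgiSat16	2414	0.07	1.12	66.8	DNA/Kolobok
CgiSat17	CgiSat17	134	0.06	0.92	76.1	DNA/Helitron
CgiSat18	CgiSat18	731	0.05	0.86	63.9	Interspersed Repeat
CgiSat19	CgiSat19	212	0.04	0.6	72.6	
CgiSat20	CgiSat20	662	0.05	0.81	65.4	
CgiSat21	CgiSat21	441	0.05	0.77	69.2	DNA/Helitron
CgiSat22	CgiSat22	743	0.04	0.66	53.3	LTR/Gypsy
CgiSat23	CgiSat23	1295	0.04	0.6	64.9	DNA/MuDR
CgiSat24	CgiSat24	66	0.04	0.58	57.6	
CgiSat25	CgiSat25	88	0.03	0.49	61.4	NonLTR/R1
CgiSat26	CgiSat26	1894	0.02	0.3	60.4	LTR/Gypsy
CgiSat27	CgiSat27	99	0.02	0.26	60.6	
CgiSat28	CgiSat28	182	0.02	0.25	44.0	DNA/MuDR
CgiSat29	CgiSat29	344	0.01	0.23	52.9	DNA/DNA4-44
CgiSat30	CgiSat30	48	0.01	0.22	68.7	
CgiSat31	CgiSat31	393	0.01	0.18	52.2	IntegratedVirus/DNAV
CgiSat32	CgiSat32	536	0.01	0.17	66.6	DNA/Mariner
CgiSat33	CgiSat33	105	0.05	0.8	46.7	
CgiSat34	CgiSat34	1423	0.04	0.57	67.3	DNA/DNA3-8
CgiSat35	CgiSat35	690	0.02	0.32	68.8	DNA/IS3EU
CgiSat36	CgiSat36	45	0.01	0.16	60.0	
CgiSat37	CgiSat37	177	0.34	5.37	56.5	DNA/Helitron
CgiSat38	CgiSat38	3287	0.1	1.58	68.0	DNA/DNA2-7
CgiSat39	CgiSat39	179	0.05	0.82	52.0	
CgiSat40	CgiSat40	673	0.04	0.65	62.9	DNA/Crypton
CgiSat41	CgiSat41	1736	0.02	0.24	66.5	DNA/Ginger1
CgiSat42	CgiSat42	930	0.03	0.52	66.9	DNA/DNA4-31
CgiSat43	CgiSat43	21	0.01	0.16	66.7	
CgiSat44	CgiSat44	748	0.01	0.16	68.6	LTR/DIRS
CgiSat45	CgiSat45	1576	0.08	1.31	64.1	DNA/DNA4-2
CgiSat46	CgiSat46	149	0.03	0.41	54.4	
CgiSat47	CgiSat47	129	0.02	0.3	69.8	DNA/IS3EU
CgiSat48	CgiSat48	2056	0.4	6.32	64.8	DNA/Helitron
CgiSat49	CgiSat49	1084	0.04	0.57	69.4	DNA/DNA2-12
CgiSat50	CgiSat50	2078	0.02	0.33	64.1	
CgiSat51	CgiSat51	396	0.01	0.19	63.1	LTR/Gypsy
CgiSat52	CgiSat52	1656	0.06	0.92	61.5	DNA/Polinton
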