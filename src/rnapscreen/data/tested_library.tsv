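accession	phage_name	temp_optimum	uniprot_id	promoter_seq	promoter_status	active	validated
R1	Prochlorococcus phage P-SSP7	14-26	Q58N45	AAAATTCTTCAAGTTTACAA	predicted	false	false
R2	Synechococcus phage S-CBP42	20	A0A096VKW2	CACTTCCACTCAACCAACCG	predicted	false	false
R3	Erwinia amylovora phage Era103	28	A2I7X6	AATAACCACCCAGTATAGAAGGAA	predicted	true	true
R4	Agrobacterium phage Atu_ph02	28	A0A223VZI2	TTATCCTTCGTATAAGGAATA	predicted	false	false
R5	Dickeya phage Mysterion	28	A0A385IGY0	CTTAAATCATCACTATTAG	predicted	true	true
R6	Pectobacterium phage PP74	30	A0A1J0MEG1	TAATACGACTCACTATTGGGAA	predicted	true	true
R7	Aquamicrobium phage P14	30	A0A1L5C074	TTTCGGTACGCTCTAGCA	predicted	false	false
R8	Pectobacterium phage DU_PP_II	30	A0A2D2W5U8	TTATTAACGACTCACTACTAGGAA	predicted	true	true
R9	Pectobacterium phage Jarilo	30	A0A2S1GSW7	TAATAACGACTCACTATTAGAAG	predicted	true	true
R10	Sphingomonas phage Scott	30	A0A346FDD2	TCGGGTTGTCGATTTCCTTAC	predicted	false	false
R11	Ralstonia phage RS-PI-1	35	A0A1S6L1D6	GTCGAAGTCGTCGAGCAGC	predicted	false	false
R12	Burkholderia phage JG068	37	U3PFP4	TCAGTAGACTATCTAG	predicted	false	false
R13	Acinetobacter phage Acibel007	37	A0A075DXW8	CTGTACTCACAGCTCAATTT	predicted	false	false
R14	Delftia phage IME-DE1	37	A0A0F7INH1	GTTAGCCCACACCATTGAAGACCC	predicted	true	true
R15	Pseudomonas phage Henninger	37	A0A2K9VHD7	TTAAAACCCTCACTATGGCTACA	predicted	true	true
R16	Pseudomonas phage PollyC	37	A0A2K9VHU7	CTCACTCACGACCCAAATTC	predicted	false	false
R17	Pseudomonas phage phiKMV	37	Q7Y2D9	CGACCCTTCCCTACTCCGGCCTTAAAT	predicted	false	false
R18	Citrobacter phage CR8	37	W6PP41	TAAGGAAGGTACACTATAGGG	predicted	true	true
R19	Thermus virus P23-45 P23p64	65	A7XX94	TTATTCCTTTA	predicted	false	false
R20	Pelagibacter phage HTVC031P	16-23	A0A4Y1NTX3	AACTAATGCTCAATTTAGAGATA	predicted	false	false
R21	Rhizobium phage RHEph01	25-30	L7TQW5	ATTACCCCTCCCTTAAGCAAAG	predicted	false	false
R22	Rhizobium phage RHEph02	25-30	L7TJC5	TTAATCCTCACTATTAGGATAA	predicted	false	false
R23	Curvibacter phage P26059B	25-30	A0A384UH57	GCAACATTACAGGTACTGAA	predicted	false	false
R24	Pseudomonas phage PPpW-4	25-30	V5YUU1	TAAAAACCCTCACTGAAACAGGG	predicted	false	false
R25	Vibrio phage 10N	35-37	A0A2I7RNL7	ACTTACCTTTCACTATAGCAGCA	predicted	false	false
R26	Alteromonas virus vB_AspP-H44	Not found	A0A220YL66	TGGTGACTACAGAGCAGCAG	predicted	false	false
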