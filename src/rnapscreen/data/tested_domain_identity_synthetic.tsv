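accession	binding_domain_identity	active
R1	6.8	false
R2	7.9	false
R3	59.4	true
R4	11.8	false
R5	50.8	true
R6	54.7	true
R7	18.6	false
R8	49.2	true
R9	34.8	true
R10	19.1	false
R11	16.9	false
R12	12.4	false
R13	36.4	false
R14	33.2	true
R15	50.8	true
R16	13.5	false
R17	41.2	false
R18	41.5	true
R19	27.7	false
R20	10.7	false
R21	27.6	false
R22	7.6	false
R23	19.4	false
R24	25.5	false
R25	26.4	false
R26	16.8	false
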