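name	phage
T7	Enterobacteria phage T7
T3	Enterobacteria phage T3
SP6	Salmonella phage SP6
KP34	Klebsiella phage KP34
Syn5	Prochlorococcus phage Syn5
VSW-3	Pseudomonas phage VSW-3
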