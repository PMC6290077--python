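# resistex integrated-table v1
transcript	DS01_FC	DS01_Q	DS02_FC	DS02_Q
AGAP000001-RA	2.41	0.003	1.92	0.012
AGAP000001-RB	2.10	0.008	1.75	0.030
AGAP000002-RA	0.48	0.001	0.55	0.004
AGAP000003-RA	1.05	0.62	NA	NA
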