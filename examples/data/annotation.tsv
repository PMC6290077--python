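# resistex probe-annotation v1
probe_id	transcript_ids	cross_hyb
P0000001	AGAP000001-RA	0
P0000002	AGAP000001-RA,AGAP000001-RB	0
P0000003	AGAP000002-RA,AGAP000009-RA	1
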