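# resistex gene-sets v1
name	member
detox_p450	AGAP000001-RA
detox_p450	AGAP000009-RA
transcription_factors	AGAP000002-RA
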