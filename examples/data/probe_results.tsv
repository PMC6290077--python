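# resistex probe-results v1
dataset_id	probe_id	fold_change	q_value
DS01	P0000001	2.41	0.003
DS01	P0000002	2.10	0.008
DS01	P0000003	0.48	0.001
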