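# resistex raw-signals v1
array_id	probe_id	red	green	dye_swapped
array_1	P0000001	5123.4	2210.9	0
array_1	P0000002	812.0	790.5	0
array_2	P0000001	2109.8	4988.1	1
array_2	P0000002	801.2	822.7	1
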