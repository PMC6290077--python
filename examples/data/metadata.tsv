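# resistex metadata v1
dataset_id	country	species	latitude	longitude	resistance_class	mortality_pct	exposure	kdr_frequency	year	comparator
DS01	Burkina Faso	coluzzii	11.189	-4.297	high	12.0	pyrethroid	0.92	2012	N'Gousso
DS02	Kenya	arabiensis	-0.417	36.951	moderate	48.5	none	NA	2011	Dongola
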