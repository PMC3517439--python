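family	genome	length_bp	copy_number	divergence_pct	divergence_sd_pct	n_sampled
Mariner-1_Tbel	Tbel	1279	400	15.0	2	183
Mariner-1_Tbel	EEu	1266	70	19.4	3	34
Mariner-1_Tbel	PBa	1285	90	6.3	1	53
Mariner-1_Tbel	HSa	1285	30	7.2	2	16
TIGGER1	Tbel	2413	80	21.2	2	27
TIGGER1	EEu	2410	47	28.0	3	25
TIGGER1	BT	2408	500	17.3	2	102
TIGGER1	TTr	2419	580	12.1	1	159
Mariner-28_SIn	SIn	1226	14	20.1	3	12
Mariner1_BT	BT	1277	400	14.7	2	95
Mariner1_BT	TTr	1285	700	7.6	1	101
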