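trait	sex	r_mz	r_dz	n_mz	n_dz
FPG	M	0.63	0.42	218	141
PG2H	M	0.57	0.45	218	141
HOMA_IR	M	0.58	0.18	218	141
FPG	F	0.71	0.50	201	81
PG2H	F	0.47	0.30	201	81
HOMA_IR	F	0.55	0.31	201	81
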