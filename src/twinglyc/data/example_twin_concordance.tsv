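trait	sex	conc_mz	conc_dz	prevalence	n_mz	n_dz
IFG	M	0.667	0.439	0.282	218	141
IGT	M	0.438	0.400	0.075	218	141
IFG	F	0.602	0.385	0.189	201	81
IGT	F	0.231	0.0001	0.065	201	81
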