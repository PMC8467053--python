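mz	log2fc	log2fc_min	log2fc_max	p	p_min	p_max
639.5	-0.61	-0.8	-0.38	0.018	0.001	0.041
683.5	-0.62	-0.67	-0.59	0.034	0.023	0.05
740.6	0.68	0.5	0.84	0.011	0.002	0.028
766.6	0.89	0.81	1.02	0.01	0.001	0.026
768.6	0.87	0.8	0.9	0.02	0.004	0.044
788.6	0.8	0.67	1.07	0.015	0.002	0.037
790.6	1.01	0.85	1.17	0.011	0.0	0.033
812.6	1.03	0.72	1.39	0.015	0.001	0.024
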