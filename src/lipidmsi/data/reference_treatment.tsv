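mz	log2fc_control_vs_treated	p	auc	group
768.6	-0.34	0.01	0.71	treated_up
784.6	-0.23	0.08	0.70	treated_up
786.6	-0.19	0.08	0.75	treated_up
790.6	-0.30	0.03	0.70	treated_up
812.6	-0.42	0.03	0.70	treated_up
604.7	1.11	0.06	0.87	control_up
779.3	0.53	0.01	0.65	control_up
801.2	0.50	0.01	0.64	control_up
867.2	0.58	0.02	0.63	control_up
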