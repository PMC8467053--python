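mz	cv_percent	accurate_mz	id	adduct	ftic_detected	tier	observed_experimentally
534.6	41		n.i.		0	none	1
548.6	50		n.i.		0	none	1
562.6	45		n.i.		0	none	1
576.7	9		n.i.		0	none	1
604.7	50		n.i.		0	none	1
609.4	14	609.340	PI 20:1	[M+H-H2O]+	1	sub_ppm	0
639.5	32	639.408	PA 32:5	[M+H]+	1	loose	0
683.5	22	683.434	PG 31:4	[M+H-H2O]+	1	loose	0
707.6	23		n.i.		0	none	1
722.5	21		n.i.		0	none	1
727.6	16	727.460	PG 33:5	[M+H]+	1	loose	0
740.6	31	740.520	PE 34:1	[M+Na]+	1	sub_ppm	1
758.6	23		n.i.		0	none	1
766.6	29	766.536	PE 36:2	[M+Na]+	1	sub_ppm	1
768.6	33	768.554	PE 38:4	[M+H]+	1	sub_ppm	1
771.6	8	771.486	PA 40:6	[M+Na]+	1	loose	0
779.3	18	779.254	n.i.		1	none	1
784.6	23		n.i.		0	none	1
786.6	23		n.i.		0	none	1
788.6	28	788.5201	PE 38:5	[M+Na]+	1	sub_ppm	1
790.6	32	790.536	PE 38:4	[M+Na]+	1	sub_ppm	1
801.2	16	801.193	n.i.		1	none	1
812.6	32	812.541	PS 36:1	[M+Na]+	1	sub_ppm	1
815.6	14		n.i.		0	none	1
826.6	8		n.i.		0	none	1
867.2	30	867.088	n.i.		1	none	1
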