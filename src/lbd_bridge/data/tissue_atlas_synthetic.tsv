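gene	heart_atrium	heart_ventricle	cerebral_cortex	cerebellum	amygdala	cingulate_cortex	nucleus_accumbens	subthalamic_nucleus	liver	blood	lung
GNB3	5.0	9.0	3.0	3.0	3.0	8.5	3.0	7.0	1.5	1.5	1.5
CNR1	8.0	4.5	4.0	9.0	4.0	4.0	8.5	4.0	1.0	1.0	1.0
MTHFR	8.0	4.5	4.0	9.0	4.0	4.0	4.0	8.0	2.0	2.0	2.0
NCAM1	8.0	5.0	9.0	4.0	8.5	4.0	4.0	4.0	1.0	1.0	1.0
LCAT	1.0	1.0	6.0	5.5	5.5	5.5	5.5	5.5	10.0	3.0	2.0
CD4	1.0	1.0	6.0	5.5	5.5	5.5	5.5	5.5	3.0	10.0	4.0
SERPINA1	1.5	1.5	6.0	5.5	5.5	5.5	5.5	5.5	10.0	8.0	4.0
IL6	2.0	2.0	5.5	5.5	5.5	5.5	5.5	5.5	3.0	10.0	6.0
PPBP	1.0	1.0	5.5	5.5	5.5	5.5	5.5	5.5	2.0	10.0	3.0
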