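gene	freq_xy	freq_yz	product_score
LPA	1	1	1
FCGR3B	2	7	14
STAR	4	1	4
ESR1	3	2	6
GNB3	4	1	4
PAG1	1	1	1
NSF	1	1	1
ESD	1	1	1
LCAT	1	1	1
DMD	3	1	3
AR	2	1	2
CNR1	1	2	2
CPAMD8	2	4	8
HLA-B	1	1	1
MTHFR	40	4	160
CD4	11	16	176
IL6	99	20	1980
RERE	1	1	1
PADI4	1	1	1
SERPINA1	1	1	1
PTPRC	8	1	8
PPBP	4	1	4
NCAM1	1	7	7
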