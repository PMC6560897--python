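disease	series	tissue	platform	n_control	n_case	genes
myocardial_infarction	GSE48060	peripheral blood	GPL570	21	31	
myocardial_infarction	GSE83500	aortic wall	GPL13667	20	17	IL-6
myocardial_infarction	GSE97320	peripheral blood	GPL570	3	3	HLA-B///PPBP///PTPRC///SERPINA1
myocardial_infarction	GSE61145	serum	GPL6106	10	14	RERE///PADI4
depression	GSE54562	anterior cingulate cortex	GPL6947	10	10	
depression	GSE54563	anterior cingulate cortex	GPL6947	25	25	FCGR3B///LPA
depression	GSE54564	amygdala	GPL6947	21	21	STAR///ESR1
depression	GSE54565	anterior cingulate cortex	GPL570	16	16	GNB3
depression	GSE54566	amygdala	GPL570	14	14	
depression	GSE54567	dorsolateral prefrontal cortex	GPL570	14	14	PAG1///NSF
depression	GSE54568	dorsolateral prefrontal cortex	GPL570	15	15	ESD///LCAT///DMD
depression	GSE54570	dorsolateral prefrontal cortex	GPL96	13	13	
depression	GSE54571	anterior cingulate cortex	GPL570	13	13	AR///CNR1///CPAMD8///HLA-B
depression	GSE54572	anterior cingulate cortex	GPL570	12	12	MTHFR///NCAM1
depression	GSE54575	orbital ventral prefrontal cortex	GPL96	12	12	CD4
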