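symbol	reason
FCGR3B	ambiguous literature term (manual inspection)
STAR	ambiguous literature term (manual inspection)
ESR1	ambiguous literature term (manual inspection)
PAG1	ambiguous literature term (manual inspection)
NSF	ambiguous literature term (manual inspection)
ESD	ambiguous literature term (manual inspection)
DMD	ambiguous literature term (manual inspection)
AR	ambiguous literature term (manual inspection)
CPAMD8	ambiguous literature term (manual inspection)
HLA-B	ambiguous literature term (manual inspection)
RERE	ambiguous literature term (manual inspection)
PADI4	ambiguous literature term (manual inspection)
PTPRC	ambiguous literature term (manual inspection)
LPA	ambiguous literature term (manual inspection)
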