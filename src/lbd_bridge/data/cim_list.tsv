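gene
LPA
FCGR3B
STAR
ESR1
GNB3
PAG1
NSF
ESD
LCAT
DMD
AR
CNR1
CPAMD8
HLA-B
MTHFR
CD4
IL6
RERE
PADI4
SERPINA1
PTPRC
PPBP
NCAM1
CIMFILL001
CIMFILL002
CIMFILL003
CIMFILL004
CIMFILL005
CIMFILL006
CIMFILL007
CIMFILL008
CIMFILL009
CIMFILL010
CIMFILL011
CIMFILL012
CIMFILL013
CIMFILL014
CIMFILL015
CIMFILL016
CIMFILL017
CIMFILL018
CIMFILL019
CIMFILL020
CIMFILL021
CIMFILL022
CIMFILL023
CIMFILL024
CIMFILL025
CIMFILL026
CIMFILL027
CIMFILL028
CIMFILL029
CIMFILL030
CIMFILL031
CIMFILL032
CIMFILL033
CIMFILL034
CIMFILL035
CIMFILL036
CIMFILL037
CIMFILL038
CIMFILL039
CIMFILL040
CIMFILL041
CIMFILL042
CIMFILL043
CIMFILL044
CIMFILL045
CIMFILL046
CIMFILL047
CIMFILL048
CIMFILL049
CIMFILL050
CIMFILL051
CIMFILL052
CIMFILL053
CIMFILL054
CIMFILL055
CIMFILL056
CIMFILL057
CIMFILL058
CIMFILL059
CIMFILL060
CIMFILL061
CIMFILL062
CIMFILL063
CIMFILL064
CIMFILL065
CIMFILL066
CIMFILL067
CIMFILL068
CIMFILL069
CIMFILL070
CIMFILL071
CIMFILL072
CIMFILL073
CIMFILL074
CIMFILL075
CIMFILL076
CIMFILL077
CIMFILL078
CIMFILL079
CIMFILL080
CIMFILL081
CIMFILL082
CIMFILL083
CIMFILL084
CIMFILL085
CIMFILL086
CIMFILL087
CIMFILL088
CIMFILL089
CIMFILL090
CIMFILL091
CIMFILL092
CIMFILL093
CIMFILL094
CIMFILL095
CIMFILL096
CIMFILL097
CIMFILL098
CIMFILL099
CIMFILL100
CIMFILL101
CIMFILL102
CIMFILL103
CIMFILL104
CIMFILL105
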