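gene	weight
MPHOSPH9	1
ADAM7	1
FOLH1	1
CD200	1
FKBP5	1
GLRA2	1
NDRG1	1
CAMKK2	1
MAN1A1	1
MED28	1
ELL2	1
ACSL3	1
PMEPA1	1
GNMT	1
ABCC4	1
HERC3	1
PIP4K2B	1
KLK3	1
EAF2	1
CENPN	1
MAPRE2	1
NKX3.1	1
KLK2	1
AR	1
TNK1	1
MAF	1
C1ORF116	1
TMPRSS2	1
TBC1D9B	1
ZBTB10	1
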