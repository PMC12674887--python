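gene	role
SLC7A11	promoter
SLC3A2	promoter
RAC1	promoter
WASF2	promoter
CYFIP1	promoter
ABI2	promoter
BRK1	promoter
NCKAP1	promoter
RPN1	promoter
SLC2A1	suppressor
SLC2A2	suppressor
SLC2A3	suppressor
SLC2A4	suppressor
SLC2A5	suppressor
SLC2A6	suppressor
SLC2A7	suppressor
SLC2A8	suppressor
SLC2A9	suppressor
SLC2A10	suppressor
SLC2A11	suppressor
SLC2A12	suppressor
SLC2A13	suppressor
SLC2A14	suppressor
SLC5A1	suppressor
SLC5A2	suppressor
SLC5A4	suppressor
SLC5A9	suppressor
SLC5A10	suppressor
SLC45A1	suppressor
G6PD	suppressor
PGD	suppressor
PGLS	suppressor
RPE	suppressor
RPIA	suppressor
TALDO1	suppressor
TKT	suppressor
GYS1	suppressor
NDUFS1	suppressor
NDUFA11	suppressor
NUBPL	suppressor
LRPPRC	suppressor
BAP1	suppressor
TXNRD1	suppressor
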