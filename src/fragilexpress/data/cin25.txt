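# CIN25 chromosomal-instability expression signature (Carter et al. 2006),
# the top 25 genes of CIN70. One gene symbol per line.
TPX2
PRC1
FOXM1
CDK1
TGIF2
MCM2
H2AZ1
TOP2A
PCNA
UBE2C
MELK
TRIP13
NCAPD2
MCM7
RNASEH2A
RAD51AP1
KIF20A
CDC45
MAD2L1
ESPL1
CCNB2
FEN1
TTK
CCT5
RFC4
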