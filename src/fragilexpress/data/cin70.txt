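# CIN70 chromosomal-instability expression signature (Carter et al. 2006),
# modern HGNC symbols. One gene symbol per line; the first 25 form CIN25.
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
ATAD2
CKAP5
NUP205
CDC20
CKS2
RRM2
ELAVL1
CCNB1
RRM1
AURKB
MSH6
EZH2
CTPS1
DKC1
OIP5
CDCA8
PTTG1
CEP55
H2AX
CMAS
NCAPH
MCM10
LSM4
NCAPG2
ASF1B
ZWINT
PBK
ZWILCH
CDCA3
ECT2
CDC6
UNG
MTCH2
RAD21
ACTL6A
PDCD2L
SRSF2
HDGF
NXT1
NEK2
DHCR7
AURKA
NDUFAB1
NCAPG
KIF4A
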