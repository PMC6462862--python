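# Consensus lung/pan-cancer driver gene list (one symbol per line)
TP53
KRAS
EGFR
BRAF
PIK3CA
STK11
KEAP1
NF1
FAT1
PTEN
RB1
CDKN2A
SETD2
ARID1A
NOTCH2
SMARCA4
MYC
CCND3
FGFR1
TP63
TSC1
WT1
ERBB2
ERBB3
ERBB4
EZH2
SOS1
SOS2
RHEB
JAK2
ATM
BRCA2
MET
ALK
ROS1
NTRK1
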