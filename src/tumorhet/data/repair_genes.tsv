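# DNA-repair genes, with emphasis on repair of tobacco-carcinogen adducts
# and oxidation-induced single-strand breaks (one symbol per line)
ERCC1
ERCC5
ERCC8
LIG4
MUTYH
NEIL1
NEIL3
POLB
RECQL4
REV1
REV3L
TDG
MBD4
RPA1
FANCA
FANCL
RAD50
RAD51B
ATM
ATR
CHEK1
BRCA1
BRCA2
XPC
OGG1
XRCC1
NTHL1
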