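gene
DNMT3A
TET2
ASXL1
NF1
IKZF1
RAD21
WT1
KMT2D
SH2B3
TP53
CEBPA
RUNX1
BCOR
KDM6A
STAG2
PHF6
KMT2C
KMT2E
PPM1D
ATRX
EZH2
CREBBP
NOTCH1
CUX1
ZRSR2
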