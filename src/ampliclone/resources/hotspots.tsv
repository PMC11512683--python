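gene	residue	required_change
CBL	366
CBL	380
CBL	384
CBL	396
CBL	404
CBL	420
DNMT3A	882
FLT3	835
IDH1	132
IDH2	140
IDH2	172
JAK2	617	V617F
KIT	557
KIT	559
KIT	816
KRAS	12
KRAS	13
KRAS	61
KRAS	146
MPL	515
NRAS	12
NRAS	13
NRAS	61
SF3B1	666
SF3B1	700
SRSF2	95
U2AF1	34
U2AF1	156
U2AF1	157
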