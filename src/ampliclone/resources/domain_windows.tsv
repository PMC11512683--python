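gene	start	end
DNMT3A	292	350
DNMT3A	482	614
DNMT3A	634	912
TET2	1104	1481
TET2	1843	2002
NOTCH1	1574	1620
NOTCH1	1671	1721
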