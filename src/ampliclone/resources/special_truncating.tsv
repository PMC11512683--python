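gene	start	end	note
CALR	352	417	exon 9
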