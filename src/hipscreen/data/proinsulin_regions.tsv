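# proinsulin regions; start/end are 1-based inclusive
label	start	end
B_chain	1	30
dibasic_RR	31	32
C_peptide	33	63
dibasic_KR	64	65
A_chain	66	86
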