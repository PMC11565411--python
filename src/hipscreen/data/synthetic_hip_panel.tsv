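# SYNTHETIC 13-member hybrid-insulin-peptide panel for fragment-origin analysis.
# Only HIP-B and HIP-G are published sequences; SYN-* rows are synthetic fusions
# constructed so the panel matches the reported aggregate origin distribution
# (N-terminal fragments: 13/13 C-peptide; C-terminal: 8 C-peptide, 3 B-chain, 1 A-chain).
hip_id	sequence	junction_index	left_seq	right_seq	note
HIP-B	GQVELGGGPIVEQCC	9	GQVELGGGP	IVEQCC	published
HIP-G	VELGGGPGAEAEDLQ	9	VELGGGPGA	EAEDLQ	published
SYN-01	ELGGGPGAGSHLVEAL	9	ELGGGPGAG	SHLVEAL	synthetic
SYN-02	LQVGQVELYTPKT	8	LQVGQVEL	YTPKT	synthetic
SYN-03	GAGSLQPLGERGF	8	GAGSLQPL	GERGF	synthetic
SYN-04	SLQPLALEKRGI	8	SLQPLALE	KRGI	synthetic
SYN-05	AEDLQVGQAGSLQP	8	AEDLQVGQ	AGSLQP	synthetic
SYN-06	VGQVELGGLALEGS	8	VGQVELGG	LALEGS	synthetic
SYN-07	LGGGPGAGSEAEDLQV	9	LGGGPGAGS	EAEDLQV	synthetic
SYN-08	QPLALEGDLQVGQ	7	QPLALEG	DLQVGQ	synthetic
SYN-09	PLALEGSLPGAGSL	8	PLALEGSL	PGAGSL	synthetic
SYN-10	EDLQVGQVGQVELG	8	EDLQVGQV	GQVELG	synthetic
SYN-11	DLQVGQVEQPLALEGSLQ	8	DLQVGQVE	QPLALEGSLQ	synthetic
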