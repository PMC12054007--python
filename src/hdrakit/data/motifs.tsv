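# Built-in motif set: name <TAB> pattern <TAB> context
# X = any residue; [..] = alternatives; context 'first:N' / 'last:N' or '.'
FeS4	CXXCXXCXXXC	.
FeS2	CXXC	.
ROSS_NAD	GXGXXG	.
ROSS_NADP	GXGXXA	.
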