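# Gene label -> canonical token used by the neighborhood rulebook.
# fwd/fmd subunits collapse to 'fwd' (formyl-methanofuran dehydrogenase);
# vhu genes are the Methanococcus naming of mvh subunits.
fwdA	fwd
fwdB	fwd
fwdC	fwd
fwdD	fwd
fwdF	fwd
fwdG	fwd
fmdA	fwd
fmdB	fwd
fmdC	fwd
fmdD	fwd
fmdE	fwd
fmdF	fwd
vhuA	mvhA
vhuD	mvhD
vhuG	mvhG
vhuU	mvhA
hdrA1	hdrA
hdrA2	hdrA
mopB	molybdop
Molybdop	molybdop
gltD-marker	gltD
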