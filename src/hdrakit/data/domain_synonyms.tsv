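# External conserved-domain accession -> controlled vocabulary label.
# Editable: the exact CD-Search output dialect varies between runs.
cl34141	TRX_FAD
GOG1148	TRX_FAD
cl48997	TRX_FAD
TRX_FAD_evidence	TRX_FAD
Fer4	FeS4
Fer2	FeS2
HdrA_FeS_N	FeS_N
HdrA_TRX_FeS	TRX_FeS
HdrA_Fd_ins	Fd_ins
HdrA_Fd_C	Fd_C
MvhD_2Fe2S	MvhD
GltD_Rossmann	GltD
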