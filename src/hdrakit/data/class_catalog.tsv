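# HdrA class catalog: class_name <TAB> major_type <TAB> space-separated domain template
# Type assignment rules: two TRX_FAD -> II; GltD -> III; terminal MvhD -> Ia; else I.
# A token suffixed '?' would mark an optional wildcard slot; the shipped
# templates are exact.  28 classes: 13 type I, 5 type Ia, 7 type II, 3 type III.
class_name	major_type	template
A0	I	TRX_FAD TRX_FeS
A1	I	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C
A1-C	I	FeS_N TRX_FAD TRX_FeS Fd_ins
A1+FeS	I	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C FeS_extra
A5	I	FeS_N TRX_FAD TRX_FeS
A6	I	TRX_FAD TRX_FeS Fd_ins
A6+FeS	I	TRX_FAD TRX_FeS Fd_ins FeS_extra
A7	I	FeS_N TRX_FAD TRX_FeS Fd_C
A8	I	TRX_FAD TRX_FeS Fd_C
A11	I	FeS_N TRX_FAD TRX_FeS FeS_extra Fd_ins Fd_C
A12	I	TRX_FAD TRX_FeS Fd_ins Fd_C
A13	I	FeS_N FeS_extra TRX_FAD TRX_FeS Fd_ins Fd_C
A14	I	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C FeS_extra FeS_extra
A2-1	Ia	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C MvhD
A2-2	Ia	TRX_FAD TRX_FeS Fd_ins Fd_C MvhD
A2-C	Ia	FeS_N TRX_FAD TRX_FeS Fd_ins MvhD
A2-5	Ia	TRX_FAD TRX_FeS Fd_ins MvhD
A2+FeS	Ia	FeS_N TRX_FAD TRX_FeS Fd_ins Fd_C FeS_extra MvhD
A3	II	FeS_N TRX_FAD TRX_FeS Fd_ins TRX_FAD TRX_FeS Fd_C
A4	II	FeS_N TRX_FAD TRX_FeS TRX_FAD TRX_FeS Fd_C
A3+MVH	II	FeS_N TRX_FAD TRX_FeS Fd_ins TRX_FAD TRX_FeS Fd_C MvhD
A3-C	II	FeS_N TRX_FAD TRX_FeS Fd_ins TRX_FAD TRX_FeS
A3-N	II	TRX_FAD TRX_FeS Fd_ins TRX_FAD TRX_FeS Fd_C
A4-C	II	FeS_N TRX_FAD TRX_FeS TRX_FAD TRX_FeS
A4+FeS	II	FeS_N TRX_FAD TRX_FeS TRX_FAD TRX_FeS Fd_C FeS_extra
A9	III	TRX_FAD TRX_FeS GltD Fd_ins
A9-TRX-C	III	TRX_FAD TRX_FeS GltD Fd_ins FeS_extra
A10	III	FeS_N TRX_FAD TRX_FeS GltD Fd_ins Fd_C
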