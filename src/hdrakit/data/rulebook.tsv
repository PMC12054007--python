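# Cluster-composition -> FBEB/FBEC prediction rulebook, most-specific-first.
# Columns: rule_id, field (mid|high|low|flag), requires (comma-separated
# tokens: gene label | hdrA=TYPE | hdrA2=TYPE | molybdop=STATUS), value,
# confidence (validated|predicted), note.
rule_id	field	requires	value	confidence	note
mid_nadh	mid	hdrA=III	NADH	predicted	type III GltD insertion repurposes the Fd site for NAD(P)H
mid_f420_molybdop	mid	fdhB,molybdop=cofactor_blocked	F420H2	predicted	FdhB with a non-catalytic structural Molybdop subunit
mid_formate	mid	fdhA,fdhB	formate	validated	Fdh-Hdr complexes oxidise formate
mid_f420	mid	fdhB	F420H2	validated	F420-dependent dehydrogenase beta subunit
mid_h2	mid	mvhA,mvhG	H2	validated	MvhAG [NiFe]-hydrogenase oxidises H2
high_hdrbc	high	hdrB,hdrC	CoM-S-S-CoB via HdrBC	validated	soluble heterodisulfide reductase arm
high_hdrd	high	hdrD	CoM-S-S-CoB via HdrD	predicted	membrane-associated HdrD arm
low_fwd	low	fwd	CO2->formyl-MFR	validated	Fwd/Fmd subunits couple low-potential electrons to CO2 reduction
low_h2ev	low	hdrA=III,mvhA,mvhG	H2-evolution	predicted	type III cluster with mvhADG may evolve H2
low_fd	low	hdrB,hdrC	Fd	validated	HdrA itself reduces ferredoxin in the complete complex
flag_two_step	flag	hdrA=II,hdrA2=I	two-step bifurcation hypothesis	predicted	a second type I hdrA may re-bifurcate low-potential electrons
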