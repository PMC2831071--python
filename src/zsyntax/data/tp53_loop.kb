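# TP53 / MDM2 regulatory loop: TP53 activates MDM2_gene transcription;
# the MDM2 protein ubiquitinates TP53, destining it for the proteasome.
# U = ubiquitin, P = proteasome, d(TP53) = degradation event.
loop1	TP53 & MDM2_gene -> TP53*MDM2_gene
loop2	TP53*MDM2_gene -> MDM2
loop3	MDM2 & TP53 -> MDM2*TP53
loop4	(MDM2*TP53) & U -> (MDM2*TP53)*U
loop5	(MDM2*TP53)*U -> MDM2 & (TP53*U)
loop6	(TP53*U) & P -> (TP53*U)*P
loop7	(TP53*U)*P -> d(TP53) & U & P
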