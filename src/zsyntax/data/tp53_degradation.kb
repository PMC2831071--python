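# Degradation path of TP53 (sub-routine of the full regulatory loop):
# MDM2 ubiquitinates TP53, ubiquitinated TP53 goes to the proteasome.
deg1	MDM2 & TP53 -> MDM2*TP53
deg2	(MDM2*TP53) & U -> (MDM2*TP53)*U
deg3	(MDM2*TP53)*U -> MDM2 & (TP53*U)
deg4	(TP53*U) & P -> (TP53*U)*P
deg5	(TP53*U)*P -> d(TP53) & U & P
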