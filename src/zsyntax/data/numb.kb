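# TP53 degradation rules plus the NUMB-MDM2 binding reaction, the setting
# for hypothesizing the NUMB / TP53 / MDM2 regulatory loop.
deg1	MDM2 & TP53 -> MDM2*TP53
deg2	(MDM2*TP53) & U -> (MDM2*TP53)*U
deg3	(MDM2*TP53)*U -> MDM2 & (TP53*U)
deg4	(TP53*U) & P -> (TP53*U)*P
deg5	(TP53*U)*P -> d(TP53) & U & P
numb1	MDM2 & NUMB -> MDM2*NUMB
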