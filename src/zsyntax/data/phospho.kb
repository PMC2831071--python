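# Phosphorylation of TP53 by an (unspecified) kinase.
# TP53-P is a distinct species from TP53.
pho1	Kinase & ATP -> Kinase*ATP
pho2	(Kinase*ATP) & TP53 -> (Kinase*ATP)*TP53
pho3	(Kinase*ATP)*TP53 -> TP53-P & Kinase & ADP
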