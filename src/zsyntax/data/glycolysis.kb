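# Glycolysis, D-Glucose to Fructose-1,6-bisphosphate
# id	rule	interaction_class	compartment	citation
gly1	Glc & HK -> Glc*HK
gly2	(Glc*HK) & ATP -> (Glc*HK)*ATP
gly3	(Glc*HK)*ATP -> G6P & HK & ADP
gly4	G6P & GPI -> G6P*GPI
gly5	G6P*GPI -> F6P & GPI
gly6	F6P & PFK -> F6P*PFK
gly7	(F6P*PFK) & ATP -> (F6P*PFK)*ATP
gly8	(F6P*PFK)*ATP -> F1,6P & PFK & ADP
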