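# Feed-forward loop: genes A_gene, B_gene, C_gene; proteins A, B, C;
# regulators RA, RB. A_gene is driven by RA; B_gene by RB together with
# protein A; C_gene by the complex A*B.
ffl1	A_gene & RA -> A_gene*RA
ffl2	A_gene*RA -> A
ffl3	A & RB -> A*RB
ffl4	(A*RB) & B_gene -> (A*RB)*B_gene
ffl5	(A*RB)*B_gene -> B
ffl6	A & B -> A*B
ffl7	(A*B) & C_gene -> (A*B)*C_gene
ffl8	(A*B)*C_gene -> C
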