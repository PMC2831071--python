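# The eight hypothetical endpoints for the NUMB / TP53 / MDM2 regulatory
# loop, from the initial aggregate TP53 & MDM2 & NUMB & U & P with the
# MDM2*NUMB complex as anchor. One candidate conclusion per line.
1	((MDM2*NUMB)*TP53) & U & P
2	(MDM2*NUMB) & U & P & TP53
3	((MDM2*NUMB)*U) & TP53 & P
4	((MDM2*NUMB)*P) & TP53 & U
5	(MDM2*NUMB) & (TP53*U) & P
6	(MDM2*NUMB) & (TP53*P) & U
7	(MDM2*NUMB) & (U*P) & TP53
8	(MDM2*NUMB) & ((TP53*P)*U)
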