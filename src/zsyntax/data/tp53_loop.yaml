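kb: tp53_loop.kb
derivation: tp53_loop_detailed.zdx
ia: "TP53 & TP53 & MDM2_gene & U & P"
goal: "d(TP53)"
reachable: true
planted_answer: null
seed: 0
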