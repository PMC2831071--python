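kb: tp53_degradation.kb
derivation: null
ia: "TP53 & MDM2 & U & P"
goal: "d(TP53)"
reachable: true
planted_answer: null
seed: 0
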