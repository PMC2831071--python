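kb: phospho.kb
derivation: null
ia: "TP53 & ATP & Kinase"
goal: "TP53-P"
reachable: true
planted_answer: null
seed: 0
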