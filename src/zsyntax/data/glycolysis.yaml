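kb: glycolysis.kb
derivation: glycolysis_detailed.zdx
ia: "Glc & HK & GPI & PFK & ATP & ATP"
goal: "F1,6P"
reachable: true
planted_answer: null
seed: 0
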