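kb: ffl.kb
derivation: ffl_detailed.zdx
ia: "A_gene & A_gene & B_gene & C_gene & RA & RA & RB"
goal: "C"
reachable: true
planted_answer: null
seed: 0
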