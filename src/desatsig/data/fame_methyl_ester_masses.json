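{
  "_comment": [
    "Molar masses (g/mol) of the fatty-acid methyl esters quantified by",
    "GC-FID, used to convert peak-area fractions into mole fractions."
  ],
  "masses": {
    "16:0": 270.45,
    "16:1": 268.43,
    "17:0": 284.48,
    "18:0": 298.50,
    "18:1": 296.49,
    "18:2": 294.47,
    "18:3": 292.46
  }
}
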