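{
  "_comment": [
    "Synthetic ungapped conserved block of the five reference enzymes",
    "(scaffold coordinates 105-185 in RcSAD1 numbering) used to build the",
    "family-triage PSSM.  The threshold is frozen at half the consensus",
    "score: all packaged references score well above it, shuffled",
    "sequences well below."
  ],
  "name": "FA_desaturase_2",
  "pseudocount": 0.5,
  "segments": [
    "KGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAALVGAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILE",
    "KGLAKAKKEMLRTLNLIEVFSMAGPKCYFYYSQLESKKADAALVGAGGESIIGSAFPSTEVQDPQCTRSIDIYFPATQILE",
    "KGLAKAKKETLRTLNLIEVFSMAGPKCYFYYSQLESKKADAALVGAGGESIIGSAFPSTEVQDPQCTRSIDIYFSAFQILE",
    "KGLAKAKKETLRTLNLIEVFSMAGPKCYFYYSQLESKKADAALVGAGGESIIGSAFPSFENQDPQCTRSIDNYFSAFQILE",
    "KGLAKAKKEMLRTWNLIEVFSMAGPKCYFYYSQLESKKADAALVGAGGTSIIGSAFPSTEVQDPQCTRSIDIYFPATQILE"
  ],
  "threshold": 114.714
}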