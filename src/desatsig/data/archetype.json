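{
  "_comment": [
    "Allowed residue sets of the omega-9 archetype pocket, ascending reference",
    "position order.  Position 115 tolerates I as well as L: three family",
    "members carry I there yet group with the archetype."
  ],
  "positions": [114, 115, 117, 118, 179, 181, 188, 189],
  "allowed": [["M"], ["L", "I"], ["T"], ["L"], ["P"], ["T"], ["G"], ["F"]]
}
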