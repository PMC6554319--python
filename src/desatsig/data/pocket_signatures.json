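{
  "_comment": [
    "Eight catalytic-pocket residues of the acyl-ACP desaturase substrate",
    "channel, in RcSAD1 reference numbering, for the five characterized",
    "reference enzymes and the 17 upland-cotton family members.",
    "Residues and printed indices are transcribed verbatim from the published",
    "comparison table, re-ordered to ascending reference position",
    "(114,115,117,118,179,181,188,189); the original print order is kept in",
    "printed_row_order.  Several printed indices are internally inconsistent",
    "with the column's own numbering offset; they are preserved as printed."
  ],
  "reference_id": "RcSAD1",
  "positions": [114, 115, 117, 118, 179, 181, 188, 189],
  "canonical_residues": "MLTLPTGF",
  "printed_row_order": [118, 189, 115, 117, 188, 181, 179, 114],
  "references": {
    "RcSAD1":  {"class": "omega9", "residues": "MLTLPTGF", "printed_indices": [114, 115, 117, 118, 179, 181, 188, 189]},
    "AtFAB2":  {"class": "omega9", "residues": "MLTLPTGF", "printed_indices": [152, 153, 155, 156, 217, 219, 226, 227]},
    "AtAAD3":  {"class": "omega7", "residues": "TLTLSFGF", "printed_indices": [149, 150, 152, 153, 214, 216, 223, 224]},
    "AtAAD2":  {"class": "omega7", "residues": "TLTLSFGF", "printed_indices": [159, 160, 162, 163, 224, 226, 233, 234]},
    "Muc-PAD": {"class": "omega7", "residues": "MLTWPTGF", "printed_indices": [148, 149, 151, 152, 213, 215, 222, 223]}
  },
  "family": {
    "GhA-SAD1": {"group": 1, "residues": "MITLPTGF", "printed_indices": [137, 138, 140, 141, 202, 204, 211, 212]},
    "GhA-SAD2": {"group": 1, "residues": "MLTLPTGF", "printed_indices": [146, 147, 149, 150, 211, 213, 210, 211]},
    "GhA-SAD3": {"group": 1, "residues": "MITLPTGF", "printed_indices": [136, 137, 139, 140, 201, 203, 210, 211]},
    "GhA-SAD4": {"group": 1, "residues": "MLTLPTGF", "printed_indices": [147, 148, 150, 151, 212, 214, 211, 212]},
    "GhA-SAD8": {"group": 1, "residues": "MLTLPTGF", "printed_indices": [146, 147, 149, 150, 211, 213, 220, 221]},
    "GhA-SAD9": {"group": 1, "residues": "MLTLPTGF", "printed_indices": [146, 147, 149, 150, 211, 213, 220, 221]},
    "GhD-SAD1": {"group": 1, "residues": "MLTLPTGF", "printed_indices": [146, 147, 149, 150, 211, 213, 220, 221]},
    "GhD-SAD2": {"group": 1, "residues": "MITLPTGF", "printed_indices": [137, 138, 140, 141, 202, 204, 211, 212]},
    "GhD-SAD3": {"group": 1, "residues": "MLTLPTGF", "printed_indices": [148, 149, 150, 151, 212, 214, 221, 222]},
    "GhD-SAD6": {"group": 1, "residues": "MLTLPTGF", "printed_indices": [146, 147, 149, 150, 211, 213, 220, 221]},
    "GhD-SAD4": {"group": 2, "residues": "ILTLPTGF", "printed_indices": [148, 149, 150, 151, 212, 214, 221, 222]},
    "GhA-SAD5": {"group": 2, "residues": "ILRLVITF", "printed_indices": [27, 28, 30, 31, 192, 94, 101, 102]},
    "GhD-SAD5": {"group": 2, "residues": "MLRLVITF", "printed_indices": [146, 147, 149, 150, 211, 213, 220, 221]},
    "GhA-SAD6": {"group": 2, "residues": "MLTLPATF", "printed_indices": [148, 149, 151, 152, 213, 215, 222, 223]},
    "GhA-SAD7": {"group": 2, "residues": "LLTMSSGA", "printed_indices": [144, 145, 147, 148, 209, 211, 218, 219]},
    "GhD-SAD7": {"group": 2, "residues": "LLTMSSGA", "printed_indices": [144, 145, 147, 148, 209, 211, 218, 219]},
    "GhD-SAD8": {"group": 2, "residues": "MLTLMAAY", "printed_indices": [147, 148, 150, 151, 212, 214, 221, 222]}
  }
}
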