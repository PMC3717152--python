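{
  "description": "Major intramolecular interactions stabilizing muscarinic receptors (M2 numbering). Each entry is a primary hydrogen-bond/salt-bridge pair; 'alternatives' are partner residues seen to substitute for residue_b in some models.",
  "entries": [
    {"label": "TM II-TM IV",  "residue_a": ["SER", 64],  "residue_b": ["ASN", 113], "alternatives": []},
    {"label": "TM II-TM IV",  "residue_a": ["SER", 64],  "residue_b": ["TRP", 148], "alternatives": []},
    {"label": "TM II-TM VII", "residue_a": ["ASP", 69],  "residue_b": ["SER", 433], "alternatives": [["TYR", 440]]},
    {"label": "TM II-TM VII", "residue_a": ["ASP", 69],  "residue_b": ["ASN", 436], "alternatives": [["TYR", 440]]},
    {"label": "TM III-o2",    "residue_a": ["ASP", 97],  "residue_b": ["GLN", 163], "alternatives": []},
    {"label": "TM III-o2",    "residue_a": ["ASP", 97],  "residue_b": ["ARG", 169], "alternatives": [["GLN", 179]]},
    {"label": "TM III-TM IV", "residue_a": ["ASN", 108], "residue_b": ["SER", 151], "alternatives": [["THR", 190]]},
    {"label": "TM III-TM IV", "residue_a": ["ASN", 108], "residue_b": ["TRP", 155], "alternatives": []},
    {"label": "TM III-TM VI", "residue_a": ["ARG", 121], "residue_b": ["GLU", 382], "alternatives": [["SER", 118], ["ASP", 120]]}
  ]
}
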