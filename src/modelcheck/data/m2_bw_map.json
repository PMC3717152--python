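{
  "receptor": "human M2 muscarinic acetylcholine receptor",
  "numbering": "Ballesteros-Weinstein helix.position -> (residue name, M2 sequence number)",
  "entries": {
    "2.45": ["SER", 64],
    "2.50": ["ASP", 69],
    "2.57": ["SER", 76],
    "3.32": ["ASP", 103],
    "3.33": ["TYR", 104],
    "3.46": ["TRP", 99],
    "3.50": ["ARG", 121],
    "5.43": ["THR", 187],
    "5.46": ["THR", 190],
    "6.30": ["GLU", 382],
    "6.51": ["TYR", 403],
    "6.52": ["ASN", 404],
    "7.39": ["TYR", 426],
    "7.43": ["TYR", 430],
    "7.49": ["ASN", 436]
  },
  "binding_site": ["2.57", "3.46", "3.32", "3.33", "5.43", "5.46", "6.51", "6.52", "7.39", "7.43"]
}
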