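{
  "L. minor": {
    "locus": "TUBB2 intron 1",
    "alignment_length": 410,
    "positions": [35, 45, 86, 175, 177, 184, 197, 206, 249, 286, 316, 330, 337, 366],
    "haplotypes": {
      "M1": "TATGCCTTACGGGA",
      "M2": "CGGTGTAGTTAAAT",
      "M3": "TATTCCTTACGGGA",
      "M4": "TATTCCTTACAGGA"
    },
    "reference": "M1"
  },
  "L. gibba": {
    "locus": "TUBB2 intron 1",
    "alignment_length": 380,
    "positions": [40, 68, 109, 224, 250, 255, 302, 329],
    "haplotypes": {
      "G1": "TTCGCTAG",
      "G2": "-TCGTTAG",
      "G3": "-AT-TCCT"
    },
    "reference": "G1"
  }
}
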