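{
  "comment": "IUPAC atomic masses: 'mono' = principal-isotope (monoisotopic) mass, 'avg' = standard atomic weight.",
  "H":  {"mono": 1.00782503207, "avg": 1.00794},
  "C":  {"mono": 12.0,          "avg": 12.0107},
  "N":  {"mono": 14.0030740048, "avg": 14.0067},
  "O":  {"mono": 15.9949146196, "avg": 15.9994},
  "S":  {"mono": 31.97207100,   "avg": 32.065},
  "Na": {"mono": 22.9897692809, "avg": 22.98976928}
}
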