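{
  "ETAS": "TACATATATGTATTATCAACATTAATGGTA",
  "CSB-D": "TATTATTAATCGAGGACATAGACATGC",
  "CSB-I": "TTGGTATTGAAGTACATAACATGCATTAAGACATATATGTA",
  "CSB-II": "CTTAAACCCCCCTACCCCCCTTAAACCCCCCGGAAACAGGGTTAAACCC",
  "CSB-III": "TGTCAAACCCCCTTACCCCCGTAAACGGGATGTC"
}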