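{
  "format": "mxprime-panel/1",
  "assay": "Brachyplatystoma COI multiplex",
  "marker": "COI",
  "primers": [
    {
      "name": "Bro385",
      "sequence": "GGGGCCATTAACTTTATC",
      "role": "species_forward",
      "target_species": "B. rousseauxii",
      "concentration_uM": 0.13
    },
    {
      "name": "Bva234",
      "sequence": "CCTACTCCTACTCGCCTCAG",
      "role": "species_forward",
      "target_species": "B. vaillantii",
      "concentration_uM": 0.07
    },
    {
      "name": "Bfi173",
      "sequence": "CACCAGATATAGCATTCCCT",
      "role": "species_forward",
      "target_species": "B. filamentosum",
      "concentration_uM": 0.07
    },
    {
      "name": "FishR1",
      "sequence": "TAGACTTCTGGGTGGCCAAAGAATCA",
      "role": "universal_reverse",
      "concentration_uM": 0.1
    },
    {
      "name": "16SL1987",
      "sequence": "GCCTCGCCTGTTTACCAAAAAC",
      "role": "control_forward",
      "concentration_uM": 0.03
    },
    {
      "name": "16SH2609",
      "sequence": "CCGGTCTGAACTCAGATCACGT",
      "role": "control_reverse",
      "concentration_uM": 0.03
    }
  ],
  "expected_bands_bp": {
    "B. rousseauxii": 254,
    "B. vaillantii": 405,
    "B. filamentosum": 466
  },
  "control_band_bp": 650
}
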