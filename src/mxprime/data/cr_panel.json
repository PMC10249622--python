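{
  "format": "mxprime-panel/1",
  "assay": "Brachyplatystoma control-region multiplex",
  "marker": "CR",
  "primers": [
    {
      "name": "Bro421",
      "sequence": "CAGGGCCACACATTTATTT",
      "role": "species_forward",
      "target_species": "B. rousseauxii",
      "concentration_uM": 0.1
    },
    {
      "name": "Bva577",
      "sequence": "CGCACGCTACCAATTATC",
      "role": "species_forward",
      "target_species": "B. vaillantii",
      "concentration_uM": 0.13
    },
    {
      "name": "Bfi742",
      "sequence": "ACCTACTATCAATCCCCCTA",
      "role": "species_forward",
      "target_species": "B. filamentosum",
      "concentration_uM": 0.1
    },
    {
      "name": "F12R",
      "sequence": "GTCAGGACCATGCCTTTGTG",
      "role": "universal_reverse",
      "concentration_uM": 0.1
    },
    {
      "name": "L2949-16S",
      "sequence": "AGTTACCCTGGGGATAACGCGCAATC",
      "role": "control_forward",
      "concentration_uM": 0.06
    },
    {
      "name": "H3058-16S",
      "sequence": "TCCGGTCTGAACTCAGATCACGTA",
      "role": "control_reverse",
      "concentration_uM": 0.06
    }
  ],
  "expected_bands_bp": {
    "B. rousseauxii": 580,
    "B. vaillantii": 451,
    "B. filamentosum": 290
  },
  "control_band_bp": 160
}
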