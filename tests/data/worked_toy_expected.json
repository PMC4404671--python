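{
  "dest_species": 0.17998077536468254,
  "diversity": {
    "S1": {
      "H_e": 0.23159722222222223,
      "H_o": 0.2833333333333333
    },
    "S2": {
      "H_e": 0.22690972222222222,
      "H_o": 0.2625
    },
    "S3": {
      "H_e": 0.15902777777777777,
      "H_o": 0.18333333333333332
    }
  },
  "kl_distances": {
    "ACC0000|ACC0001": 0.20588235294117646,
    "ACC0000|ACC0004": 0.4444444444444444,
    "ACC0000|ACC0008": 0.34375
  },
  "n_accessions": 12,
  "n_admissible_loci_g2": 20,
  "n_markers": 20,
  "richness_g2": {
    "S1": 1.265952380952381,
    "S2": 1.2620238095238094,
    "S3": 1.1833333333333331
  }
}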