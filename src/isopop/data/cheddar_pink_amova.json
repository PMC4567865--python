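{
  "description": "Published AMOVA summaries (df, sums of squares) and per-population sample sizes for the two-region Cheddar pink survey (20 populations, 297 individuals, 308 dominant loci).",
  "sample_sizes": {
    "Switzerland": [15, 15, 15, 15, 15, 15, 15, 15, 15, 15],
    "Germany": [15, 15, 15, 15, 15, 15, 12, 15, 15, 15]
  },
  "analyses": {
    "three_level": {
      "strata": [
        ["Among regions", 1, 1108.988],
        ["Among populations within regions", 18, 3639.084],
        ["Within populations", 277, 6727.767]
      ]
    },
    "all_populations": {
      "strata": [
        ["Among populations", 19, 4748.072],
        ["Within populations", 277, 6727.767]
      ]
    },
    "switzerland": {
      "strata": [
        ["Among populations", 9, 1578.940],
        ["Within populations", 140, 3497.067]
      ]
    },
    "germany": {
      "strata": [
        ["Among populations", 9, 2060.144],
        ["Within populations", 137, 3230.700]
      ]
    }
  }
}
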