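{
  "_comment": [
    "Direct-social genetic parameter sets for survival time (days) in",
    "purebred and crossbred laying hens housed in 4-bird cages.",
    "RECONSTRUCTED values: the original supplementary estimates were not",
    "available, so these sets were obtained by least-squares inversion of",
    "the published predicted selection responses (unit intensity) through",
    "this package's accuracy formulas, constrained to valid (positive",
    "semidefinite) parameter configurations and to the published ranges of",
    "sd(TBV), T2 and rA.  The published response table is not exactly",
    "consistent with any single valid parameter configuration (see",
    "docs/methods.md), so reproduction is approximate: the worst cell",
    "deviates by ~0.6 days (purebred) / ~0.8 days (crossbred); the",
    "individual-selection rows are reproduced to < 0.01 days."
  ],
  "trait": "survival time, days",
  "group_size": 4,
  "populations": {
    "purebred": {
      "lines": [
        {
          "label": "purebred (reconstructed, pooled)",
          "var_direct_genetic": 1661.0,
          "var_social_genetic": 210.0,
          "cov_direct_social_genetic": -183.1,
          "var_direct_residual": 4415.6,
          "var_social_residual": 2136.5,
          "cov_direct_social_residual": -1617.8,
          "var_group_env": 24.2
        }
      ]
    },
    "crossbred": {
      "lines": [
        {
          "label": "crossbred (reconstructed, pooled)",
          "var_direct_genetic": 1110.9,
          "var_social_genetic": 740.7,
          "cov_direct_social_genetic": -740.7,
          "var_direct_residual": 11840.5,
          "var_social_residual": 1188.3,
          "cov_direct_social_residual": 26.5,
          "var_group_env": 79.8
        }
      ]
    }
  }
}
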