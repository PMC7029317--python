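{
  "description": "Published 95% confidence intervals for 12-week score changes (follow-up minus baseline) per baseline-CDR stratum, with stratum sizes. The CDR 0.5/0 stratum size carries an unexplained asterisk in the source table; it is recorded as printed and flagged.",
  "strata": [
    {
      "stratum": "CDR 3", "cdr_levels": [3.0], "n": 33, "flag": null,
      "measures": {
        "adl":     {"ci_lower": -1.87,  "ci_upper": 0.21},
        "bpsd":    {"ci_lower": -2.51,  "ci_upper": 1.40},
        "cf":      {"ci_lower": -0.93,  "ci_upper": 1.26},
        "total":   {"ci_lower": -4.18,  "ci_upper": 1.73},
        "tdd":     {"ci_lower": -2.52,  "ci_upper": 0.83},
        "dad":     {"ci_lower": -24.88, "ci_upper": 5.12},
        "npi":     {"ci_lower": -8.83,  "ci_upper": 0.72},
        "mmse":    {"ci_lower": -0.29,  "ci_upper": 0.63},
        "cdr_sob": {"ci_lower": -0.03,  "ci_upper": 0.81}
      }
    },
    {
      "stratum": "CDR 2", "cdr_levels": [2.0], "n": 65, "flag": null,
      "measures": {
        "adl":     {"ci_lower": -2.83, "ci_upper": -0.27},
        "bpsd":    {"ci_lower": -0.24, "ci_upper": 1.64},
        "cf":      {"ci_lower": -2.58, "ci_upper": -0.12},
        "total":   {"ci_lower": -4.55, "ci_upper": 0.15},
        "tdd":     {"ci_lower": -2.70, "ci_upper": -0.04},
        "dad":     {"ci_lower": -6.68, "ci_upper": -1.25},
        "npi":     {"ci_lower": -2.68, "ci_upper": 4.28},
        "mmse":    {"ci_lower": -1.46, "ci_upper": 0.16},
        "cdr_sob": {"ci_lower": 0.33,  "ci_upper": 1.27}
      }
    },
    {
      "stratum": "CDR 1", "cdr_levels": [1.0], "n": 99, "flag": null,
      "measures": {
        "adl":     {"ci_lower": -2.11, "ci_upper": -0.31},
        "bpsd":    {"ci_lower": -0.06, "ci_upper": 1.02},
        "cf":      {"ci_lower": -1.82, "ci_upper": 0.01},
        "total":   {"ci_lower": -3.09, "ci_upper": 0.01},
        "tdd":     {"ci_lower": -2.03, "ci_upper": -0.20},
        "dad":     {"ci_lower": -9.42, "ci_upper": -3.78},
        "npi":     {"ci_lower": -1.79, "ci_upper": 2.32},
        "mmse":    {"ci_lower": -1.31, "ci_upper": -0.10},
        "cdr_sob": {"ci_lower": 0.13,  "ci_upper": 0.71}
      }
    },
    {
      "stratum": "CDR 0.5/0", "cdr_levels": [0.5, 0.0], "n": 114, "flag": "asterisk in source",
      "measures": {
        "adl":     {"ci_lower": -1.21, "ci_upper": 0.01},
        "bpsd":    {"ci_lower": -0.60, "ci_upper": 0.11},
        "cf":      {"ci_lower": -1.56, "ci_upper": -0.23},
        "total":   {"ci_lower": -2.81, "ci_upper": -0.67},
        "tdd":     {"ci_lower": -1.55, "ci_upper": -0.31},
        "dad":     {"ci_lower": -5.58, "ci_upper": -0.27},
        "npi":     {"ci_lower": -0.79, "ci_upper": 1.91},
        "mmse":    {"ci_lower": -0.58, "ci_upper": 0.51},
        "cdr_sob": {"ci_lower": -0.15, "ci_upper": 0.27}
      }
    }
  ]
}
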