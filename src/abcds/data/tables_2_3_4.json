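{
  "description": "Published per-subgroup six-statistic summaries (min, q1, median, mean, q3, max) of ABC-DS domain scores, TDD, and CDR-SOB for baseline CDR strata 1, 2, and 3.",
  "subgroups": [
    {
      "name": "C1.1", "stratum": 1, "n": 27,
      "adl":     {"min": 40.0, "q1": 48.0, "median": 50.0, "mean": 49.7, "q3": 52.0, "max": 54.0},
      "bpsd":    {"min": 20.0, "q1": 24.0, "median": 26.0, "mean": 25.2, "q3": 27.0, "max": 27.0},
      "cf":      {"min": 19.0, "q1": 22.0, "median": 25.0, "mean": 24.6, "q3": 26.5, "max": 32.0},
      "tdd":     {"min": 51.6, "q1": 58.8, "median": 61.1, "mean": 61.0, "q3": 62.9, "max": 68.3},
      "cdr_sob": {"min": 4.5,  "q1": 5.0,  "median": 5.0,  "mean": 5.9,  "q3": 7.0,  "max": 9.0}
    },
    {
      "name": "C1.2", "stratum": 1, "n": 41,
      "adl":     {"min": 37.0, "q1": 48.0, "median": 50.0, "mean": 49.1, "q3": 52.0, "max": 54.0},
      "bpsd":    {"min": 19.0, "q1": 24.0, "median": 25.0, "mean": 24.9, "q3": 27.0, "max": 27.0},
      "cf":      {"min": 10.0, "q1": 16.0, "median": 17.0, "mean": 17.7, "q3": 19.0, "max": 28.0},
      "tdd":     {"min": 48.4, "q1": 56.0, "median": 58.5, "mean": 58.0, "q3": 60.1, "max": 64.1},
      "cdr_sob": {"min": 4.0,  "q1": 6.0,  "median": 7.0,  "mean": 6.9,  "q3": 8.0,  "max": 10.0}
    },
    {
      "name": "C1.3", "stratum": 1, "n": 11,
      "adl":     {"min": 35.0, "q1": 41.0, "median": 43.0, "mean": 43.7, "q3": 47.5, "max": 50.0},
      "bpsd":    {"min": 15.0, "q1": 16.5, "median": 18.0, "mean": 18.9, "q3": 21.5, "max": 25.0},
      "cf":      {"min": 11.0, "q1": 14.0, "median": 16.0, "mean": 16.3, "q3": 16.5, "max": 28.0},
      "tdd":     {"min": 41.4, "q1": 48.6, "median": 50.6, "mean": 50.6, "q3": 53.1, "max": 59.2},
      "cdr_sob": {"min": 4.5,  "q1": 5.3,  "median": 6.0,  "mean": 6.4,  "q3": 7.5,  "max": 10.0}
    },
    {
      "name": "C1.4", "stratum": 1, "n": 20,
      "adl":     {"min": 26.0, "q1": 35.0, "median": 38.0, "mean": 37.8, "q3": 40.3, "max": 44.0},
      "bpsd":    {"min": 13.0, "q1": 21.0, "median": 22.5, "mean": 22.3, "q3": 25.0, "max": 27.0},
      "cf":      {"min": 7.0,  "q1": 9.8,  "median": 12.5, "mean": 12.5, "q3": 14.0, "max": 20.0},
      "tdd":     {"min": 38.0, "q1": 42.6, "median": 46.0, "mean": 45.8, "q3": 49.4, "max": 52.1},
      "cdr_sob": {"min": 4.0,  "q1": 6.0,  "median": 7.8,  "mean": 7.4,  "q3": 9.0,  "max": 10.0}
    },
    {
      "name": "C2.1", "stratum": 2, "n": 9,
      "adl":     {"min": 42.0, "q1": 46.0, "median": 48.0, "mean": 47.4, "q3": 49.0, "max": 54.0},
      "bpsd":    {"min": 22.0, "q1": 25.0, "median": 26.0, "mean": 25.7, "q3": 27.0, "max": 27.0},
      "cf":      {"min": 20.0, "q1": 20.0, "median": 22.0, "mean": 22.7, "q3": 24.0, "max": 26.0},
      "tdd":     {"min": 54.6, "q1": 57.0, "median": 58.8, "mean": 58.6, "q3": 59.8, "max": 63.6},
      "cdr_sob": {"min": 9.0,  "q1": 10.0, "median": 11.0, "mean": 10.7, "q3": 11.0, "max": 13.0}
    },
    {
      "name": "C2.2", "stratum": 2, "n": 23,
      "adl":     {"min": 36.0, "q1": 42.5, "median": 46.0, "mean": 46.0, "q3": 50.0, "max": 54.0},
      "bpsd":    {"min": 21.0, "q1": 24.0, "median": 25.0, "mean": 25.1, "q3": 27.0, "max": 27.0},
      "cf":      {"min": 12.0, "q1": 14.0, "median": 16.0, "mean": 16.3, "q3": 18.0, "max": 22.0},
      "tdd":     {"min": 46.1, "q1": 51.9, "median": 54.7, "mean": 55.0, "q3": 58.3, "max": 64.3},
      "cdr_sob": {"min": 9.0,  "q1": 10.0, "median": 10.5, "mean": 10.7, "q3": 11.0, "max": 14.0}
    },
    {
      "name": "C2.3", "stratum": 2, "n": 17,
      "adl":     {"min": 28.0, "q1": 36.0, "median": 37.0, "mean": 38.4, "q3": 42.0, "max": 45.0},
      "bpsd":    {"min": 12.0, "q1": 19.0, "median": 22.0, "mean": 21.3, "q3": 24.0, "max": 27.0},
      "cf":      {"min": 7.0,  "q1": 8.0,  "median": 10.0, "mean": 10.4, "q3": 12.0, "max": 16.0},
      "tdd":     {"min": 33.0, "q1": 44.0, "median": 46.2, "mean": 45.3, "q3": 48.9, "max": 51.3},
      "cdr_sob": {"min": 10.0, "q1": 11.0, "median": 12.0, "mean": 12.2, "q3": 13.0, "max": 14.0}
    },
    {
      "name": "C2.4", "stratum": 2, "n": 11,
      "adl":     {"min": 21.0, "q1": 28.5, "median": 30.0, "mean": 30.5, "q3": 32.5, "max": 38.0},
      "bpsd":    {"min": 22.0, "q1": 23.0, "median": 24.0, "mean": 24.6, "q3": 26.0, "max": 27.0},
      "cf":      {"min": 9.0,  "q1": 11.0, "median": 14.0, "mean": 15.2, "q3": 20.0, "max": 21.0},
      "tdd":     {"min": 35.4, "q1": 40.0, "median": 41.6, "mean": 42.3, "q3": 44.4, "max": 49.7},
      "cdr_sob": {"min": 8.5,  "q1": 10.5, "median": 11.0, "mean": 11.2, "q3": 12.5, "max": 14.0}
    },
    {
      "name": "C2.5", "stratum": 2, "n": 5,
      "adl":     {"min": 22.0, "q1": 24.0, "median": 26.0, "mean": 27.2, "q3": 31.0, "max": 33.0},
      "bpsd":    {"min": 11.0, "q1": 16.0, "median": 16.0, "mean": 17.0, "q3": 21.0, "max": 21.0},
      "cf":      {"min": 6.0,  "q1": 6.0,  "median": 6.0,  "mean": 6.8,  "q3": 8.0,  "max": 8.0},
      "tdd":     {"min": 27.9, "q1": 32.5, "median": 33.4, "mean": 33.1, "q3": 34.4, "max": 37.5},
      "cdr_sob": {"min": 12.0, "q1": 13.0, "median": 14.0, "mean": 13.6, "q3": 14.0, "max": 15.0}
    },
    {
      "name": "C3.1", "stratum": 3, "n": 10,
      "adl":     {"min": 23.0, "q1": 26.0, "median": 31.0, "mean": 31.4, "q3": 35.5, "max": 42.0},
      "bpsd":    {"min": 9.0,  "q1": 12.5, "median": 15.0, "mean": 15.0, "q3": 17.3, "max": 22.0},
      "cf":      {"min": 4.0,  "q1": 6.0,  "median": 9.0,  "mean": 8.4,  "q3": 10.0, "max": 14.0},
      "tdd":     {"min": 27.2, "q1": 32.2, "median": 36.7, "mean": 36.2, "q3": 38.9, "max": 46.2},
      "cdr_sob": {"min": 15.0, "q1": 15.3, "median": 17.0, "mean": 16.4, "q3": 17.0, "max": 18.0}
    },
    {
      "name": "C3.2", "stratum": 3, "n": 17,
      "adl":     {"min": 12.0, "q1": 16.0, "median": 24.0, "mean": 21.9, "q3": 27.0, "max": 37.0},
      "bpsd":    {"min": 18.0, "q1": 23.0, "median": 25.0, "mean": 23.9, "q3": 25.0, "max": 27.0},
      "cf":      {"min": 4.0,  "q1": 4.0,  "median": 8.0,  "mean": 9.1,  "q3": 10.0, "max": 22.0},
      "tdd":     {"min": 22.0, "q1": 30.6, "median": 34.2, "mean": 34.4, "q3": 37.7, "max": 49.8},
      "cdr_sob": {"min": 14.0, "q1": 16.0, "median": 18.0, "mean": 16.9, "q3": 18.0, "max": 18.0}
    },
    {
      "name": "C3.3", "stratum": 3, "n": 6,
      "adl":     {"min": 8.0,  "q1": 8.3,  "median": 10.5, "mean": 10.8, "q3": 13.5, "max": 14.0},
      "bpsd":    {"min": 3.0,  "q1": 7.5,  "median": 9.0,  "mean": 8.8,  "q3": 11.3, "max": 13.0},
      "cf":      {"min": 4.0,  "q1": 4.5,  "median": 6.0,  "mean": 5.3,  "q3": 6.0,  "max": 6.0},
      "tdd":     {"min": 10.4, "q1": 13.6, "median": 15.1, "mean": 15.3, "q3": 18.1, "max": 18.9},
      "cdr_sob": {"min": 17.0, "q1": 18.0, "median": 18.0, "mean": 17.8, "q3": 18.0, "max": 18.0}
    }
  ]
}
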