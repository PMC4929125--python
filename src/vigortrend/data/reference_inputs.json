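{
  "comment": "Published ratio/baseline inputs used by the repro-tables subcommand. 'printed_*' fields are the values as displayed at source precision; rows flagged known_discrepancy differ from recomputation at the printed 3-dp ratio by one unit in the last place (presumably computed from the unrounded fitted ratio).",
  "years": 13,
  "overall_n": 24025,
  "baseline_band_n": 1303,
  "rows": [
    {"table": "single", "label": "VPA", "ratio": 0.931, "ci": [0.925, 0.938], "baseline_mean": 12.97, "baseline_sd": 12.64, "printed_pct": -6.9, "printed_change": -7.85, "n": 24025},
    {"table": "single", "label": "MPA", "ratio": 0.940, "ci": [0.936, 0.944], "baseline_mean": 41.32, "baseline_sd": 17.46, "printed_pct": -6.0, "printed_change": -22.83, "n": 24025},
    {"table": "adjusted", "label": "VPA", "ratio": 0.989, "ci": [0.984, 0.994], "baseline_mean": null, "printed_pct": -1.1, "printed_change": null, "n": 24025},
    {"table": "adjusted", "label": "MPA", "ratio": 1.036, "ci": [1.035, 1.036], "baseline_mean": null, "printed_pct": 3.6, "printed_change": null, "n": 24025},
    {"table": "strata", "moderator": "sex", "label": "male", "ratio": 0.971, "ci": [0.962, 0.980], "baseline_mean": 15.16, "baseline_sd": 15.03, "printed_pct": -2.9, "printed_change": -4.82},
    {"table": "strata", "moderator": "sex", "label": "female", "ratio": 0.893, "ci": [0.884, 0.901], "baseline_mean": 10.98, "baseline_sd": 9.56, "printed_pct": -10.7, "printed_change": -8.46},
    {"table": "strata", "moderator": "ethnicity", "label": "white", "ratio": 0.939, "baseline_mean": 10.58, "baseline_sd": 8.43, "printed_pct": -6.1, "printed_change": null},
    {"table": "strata", "moderator": "ethnicity", "label": "black", "ratio": 0.871, "baseline_mean": null, "printed_pct": -12.9, "printed_change": null},
    {"table": "strata", "moderator": "ethnicity", "label": "Hispanic", "ratio": 0.906, "baseline_mean": null, "printed_pct": -9.4, "printed_change": null},
    {"table": "strata", "moderator": "ethnicity", "label": "other", "ratio": 0.906, "baseline_mean": null, "printed_pct": -9.4, "printed_change": null},
    {"table": "strata", "moderator": "maternal_education", "label": "high school", "ratio": 0.980, "baseline_mean": 17.91, "baseline_sd": 14.9, "printed_pct": -2.0, "printed_change": -4.14},
    {"table": "strata", "moderator": "weight_status", "label": "normal", "ratio": 0.939, "baseline_mean": 12.85, "baseline_sd": 12.34, "printed_pct": -6.1, "printed_change": -7.18},
    {"table": "strata", "moderator": "weight_status", "label": "overweight/obese", "ratio": 0.919, "baseline_mean": 11.71, "baseline_sd": 10.16, "printed_pct": -8.1, "printed_change": -7.80},
    {"table": "strata", "moderator": "region", "label": "UK", "ratio": 1.065, "ci": [1.041, 1.089], "baseline_mean": 13.60, "baseline_sd": 12.45, "printed_pct": 6.5, "printed_change": 17.24, "n": 9767},
    {"table": "strata", "moderator": "region", "label": "North America", "ratio": 0.885, "baseline_mean": 11.18, "baseline_sd": 8.31, "printed_pct": -11.5, "printed_change": -8.90},
    {"table": "strata", "moderator": "region", "label": "Australia", "ratio": 0.979, "baseline_mean": 19.78, "baseline_sd": 16.06, "printed_pct": -2.1, "printed_change": -4.78, "known_discrepancy": true}
  ]
}
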