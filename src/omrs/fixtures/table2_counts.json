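{
  "description": "2x2 progression tables for the 62-patient leukoplakia prognostic cohort. Cells: a = exposed progressed, b = exposed not progressed, c = unexposed progressed, d = unexposed not progressed. The AVEH and dysplasia rows total fewer than 62 because of missing chart data.",
  "n_patients": 62,
  "n_progressed": 26,
  "tables": {
    "omrs_risk": {"exposed": "high_risk", "unexposed": "low_risk", "a": 18, "b": 13, "c": 8, "d": 23},
    "site": {"exposed": "tongue", "unexposed": "other_sites", "a": 23, "b": 20, "c": 3, "d": 16},
    "gender": {"exposed": "female", "unexposed": "male", "a": 16, "b": 14, "c": 10, "d": 22},
    "prior_oscc": {"exposed": "yes", "unexposed": "no", "a": 9, "b": 9, "c": 17, "d": 27},
    "aveh": {"exposed": "present", "unexposed": "absent", "a": 4, "b": 12, "c": 18, "d": 23},
    "dysplasia": {"exposed": "moderate_severe", "unexposed": "none_mild", "a": 16, "b": 16, "c": 6, "d": 19}
  }
}
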