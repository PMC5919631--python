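{
  "_comment": [
    "Encoded protocols of the six published validation studies used as",
    "simulation fixtures. Sex counts, age (y), body weight (kg), height (m)",
    "ranges, imposed VO2max (ml/kg/min), exercise segments (duration min at",
    "Tv %VO2max) and the observables each study reported. Heights are stored",
    "for provenance only; no model equation consumes them. Segments flagged",
    "above_lt exceed the lactate threshold, outside the model's validity",
    "domain."
  ],
  "studies": [
    {
      "study_id": 1,
      "label": "incremental cycling, four 8-min stages",
      "groups": [
        {"label": "untrained", "n_male": 6, "n_female": 0,
         "age": [28, 30], "body_weight": [70, 78], "height": [1.80, 1.88],
         "vo2max": 35},
        {"label": "trained", "n_male": 6, "n_female": 0,
         "age": [25, 27], "body_weight": [65, 73], "height": [1.72, 1.78],
         "vo2max": 50}
      ],
      "protocols": [
        {"label": "incremental", "baseline_min": 0, "recovery_min": 60,
         "segments": [
           {"duration_min": 8, "tv": 38},
           {"duration_min": 8, "tv": 51},
           {"duration_min": 8, "tv": 64},
           {"duration_min": 8, "tv": 77, "above_lt": true}
         ]}
      ],
      "observables": {"hormones": ["glucagon", "epinephrine", "insulin"],
                      "substrates": ["glucose", "glycerol", "lactate", "ffa",
                                     "alanine"]},
      "notes": "Segment length 8 min per the protocol table; the narrative description gives four 7-min periods (seven_minute_variant flag). Stage intensities 38/51/64/77 %VO2max are the published conversions of 30/45/60/75 %Wmax; the final stage is above the lactate threshold (dark zone until min 32)."
    },
    {
      "study_id": 2,
      "label": "40 min constant cycling at Tv 60",
      "groups": [
        {"label": "all", "n_male": 8, "n_female": 0,
         "age": [23, 40], "body_weight": [71, 89], "height": [1.74, 1.88],
         "vo2max": 46}
      ],
      "protocols": [
        {"label": "constant", "baseline_min": 0, "recovery_min": 60,
         "segments": [{"duration_min": 40, "tv": 60}]}
      ],
      "observables": {"hormones": ["glucagon"],
                      "substrates": ["glucose", "glycerol", "lactate", "ffa"]}
    },
    {
      "study_id": 3,
      "label": "60 min constant cycling at Tv 60 (estimation dataset)",
      "groups": [
        {"label": "all", "n_male": 13, "n_female": 0,
         "age": [22, 28], "body_weight": [66, 85], "height": [1.80, 1.80],
         "vo2max": 44}
      ],
      "protocols": [
        {"label": "constant", "baseline_min": 30, "recovery_min": 120,
         "segments": [{"duration_min": 60, "tv": 60}]}
      ],
      "observables": {"hormones": ["insulin", "glucagon", "epinephrine"],
                      "substrates": ["ffa"]},
      "notes": "30 min baseline before onset and 120 min recovery after; insulin and glucagon used for coupling-parameter estimation. Height is an imposed value, not reported by the study."
    },
    {
      "study_id": 4,
      "label": "120 min constant cycling at Tv 40",
      "groups": [
        {"label": "untrained", "n_male": 7, "n_female": 0,
         "age": [21, 23], "body_weight": [69, 82], "height": [1.80, 1.80],
         "vo2max": 39},
        {"label": "trained", "n_male": 7, "n_female": 0,
         "age": [25, 27], "body_weight": [69, 82], "height": [1.80, 1.80],
         "vo2max": 58}
      ],
      "protocols": [
        {"label": "constant", "baseline_min": 0, "recovery_min": 60,
         "segments": [{"duration_min": 120, "tv": 40}]}
      ],
      "observables": {"hormones": [], "substrates": ["lactate"]},
      "notes": "Heights are imposed values, not reported by the study."
    },
    {
      "study_id": 5,
      "label": "90 min constant cycling at Tv 60, male and female groups",
      "groups": [
        {"label": "male", "n_male": 8, "n_female": 0,
         "age": [21, 23], "body_weight": [76, 81], "height": [1.73, 1.79],
         "vo2max": 42},
        {"label": "female", "n_male": 0, "n_female": 8,
         "age": [21, 23], "body_weight": [64, 70], "height": [1.64, 1.66],
         "vo2max": 32}
      ],
      "protocols": [
        {"label": "constant", "baseline_min": 0, "recovery_min": 60,
         "segments": [{"duration_min": 90, "tv": 60}]}
      ],
      "observables": {"hormones": ["epinephrine"],
                      "substrates": ["glycerol", "lactate", "ffa"]}
    },
    {
      "study_id": 6,
      "label": "prolonged cycling: 180 min at Tv 31 and 120 min at Tv 64",
      "groups": [
        {"label": "all", "n_male": 13, "n_female": 0,
         "age": [20, 30], "body_weight": [64, 84], "height": [1.69, 1.93],
         "vo2max": 61}
      ],
      "protocols": [
        {"label": "low_intensity", "baseline_min": 0, "recovery_min": 60,
         "segments": [{"duration_min": 180, "tv": 31}]},
        {"label": "moderate_intensity", "baseline_min": 0, "recovery_min": 60,
         "segments": [{"duration_min": 120, "tv": 64}]}
      ],
      "observables": {"hormones": [], "substrates": ["muscle_glycogen"]},
      "unsupported_observables": ["muscle_glycogen"],
      "notes": "Muscle glycogen requires the out-of-scope multi-organ metabolic core; the protocol is encoded but the observable cannot be simulated here."
    }
  ]
}
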