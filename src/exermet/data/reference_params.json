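{
  "_comment": [
    "Reference model configuration for the exercise hormone layer.",
    "Epinephrine secretion/elimination block: Vd_L volume of distribution (L);",
    "f1 basal secretion and the two sigmoid blocks (glucose: c1,c2,c3; exercise:",
    "d1,d2,d3) in pmol.kg-1.min-1 / L.mmol-1 / mmol.L-1 and pmol.kg-1.min-1 /",
    "per-%VO2max / %VO2max respectively; ce0_pM basal plasma epinephrine;",
    "cag_star_mM fasting arterial glucose. Controller block: basal insulin and",
    "glucagon (pM), interaction gains k1..k4 (pM-1.min-1 under constant-one",
    "glucose modulation), epinephrine->insulin coupling k5 (pM-1.min-1) and the",
    "first-order turnover rate D (min-1). The elimination constant k and the",
    "controller offset h are DERIVED at run time from steady-state calibration",
    "and are never read from this file. Values of unprinted constants are",
    "documented model defaults chosen for physiological plausibility (see",
    "docs/methods.md); k5 is the published coupling estimate."
  ],
  "epinephrine": {
    "vd": 20.0,
    "f1": 10.0,
    "c1": 40.0,
    "c2": 2.0,
    "c3": 3.0,
    "d1": 115.0,
    "d2": 0.1,
    "d3": 60.0,
    "ce0": 400.0,
    "cag_star": 5.0
  },
  "controller": {
    "ci0": 60.0,
    "cg0": 30.0,
    "k1": 0.008,
    "k2": 0.004,
    "k3": 0.002,
    "k4": 0.004,
    "k5": 3.6e-05,
    "d_rate": 0.1
  },
  "oxygen": {
    "rate": 0.8
  }
}
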