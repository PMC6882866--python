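{
 "description": "Reference exclusion ledger for an 11-session, 32-channel micro-ECoG benchmark acquisition: per-session channel notes (discontinuities, weak bimodality) and excluded channels with reasons, plus the number of additional channels removed by the pooled peak-width stability screen.",
 "sessions": [
  {"id": "01", "hemisphere": "R", "duration_s": 304.102,
   "excluded": {"8": "sd_outlier"}},
  {"id": "02", "hemisphere": "R", "duration_s": 300.912,
   "weak_bimodality": [1, 2, 3, 4, 7, 9, 10, 11, 12, 14, 15, 16, 17, 18, 19, 20, 22, 23, 24, 25, 26, 27, 28, 29],
   "excluded": {"30": "daq_failure", "31": "daq_failure", "32": "daq_failure"}},
  {"id": "03", "hemisphere": "L", "duration_s": 427.223,
   "discontinuity": [2, 4, 8, 12, 15, 19, 20, 23, 28, 31, 32],
   "excluded": {"3": "sd_outlier", "13": "sd_outlier"}},
  {"id": "07", "hemisphere": "L", "duration_s": 351.701,
   "excluded": {}},
  {"id": "09", "hemisphere": "L", "duration_s": 321.942,
   "discontinuity": [23],
   "weak_bimodality": [2, 3, 17, 20],
   "excluded": {"3": "sd_outlier", "9": "sd_outlier"}},
  {"id": "10", "hemisphere": "L", "duration_s": 309.19,
   "discontinuity": [12],
   "excluded": {"12": "daq_failure"}},
  {"id": "14", "hemisphere": "R", "duration_s": 313.714,
   "excluded": {}},
  {"id": "15", "hemisphere": "R", "duration_s": 329.605,
   "excluded": {"25": "sd_outlier"}},
  {"id": "16", "hemisphere": "R", "duration_s": 312.157,
   "discontinuity": [14],
   "excluded": {"4": "sd_outlier", "31": "daq_failure"}},
  {"id": "17", "hemisphere": "R", "duration_s": 305.967,
   "excluded": {}},
  {"id": "20", "hemisphere": "R", "duration_s": 319.942,
   "excluded": {"1": "negative_asymmetry", "12": "sd_outlier", "25": "sd_outlier"}}
 ],
 "stability_screen_additional": 12
}
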