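{
 "name": "toy",
 "model_id": "at_biopsy",
 "variant": "without_race",
 "provenance": "Toy set for tests and documentation examples.",
 "terms": [
  {
   "covariate": "proteinuria_g_day",
   "transform": "log",
   "center": 0.0,
   "coef": 0.5
  },
  {
   "covariate": "egfr",
   "transform": "identity",
   "center": 76.0,
   "coef": -0.02
  }
 ],
 "baseline_survival": [
  [
   0,
   1.0
  ],
  [
   36,
   0.95
  ],
  [
   60,
   0.9
  ],
  [
   80,
   0.85
  ]
 ]
}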