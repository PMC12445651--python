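{
 "name": "synthetic_post_biopsy_with_race",
 "model_id": "post_biopsy",
 "variant": "with_race",
 "provenance": "Synthetic stand-in coefficient set: magnitudes chosen to mimic the published tool's covariate structure and discrimination; NOT the published IIgAN-PT constants. Baseline survival is Weibull (shape 1.8, scale 162.0 months).",
 "terms": [
  {
   "covariate": "proteinuria_g_day",
   "transform": "log",
   "center": 0.3365,
   "coef": 0.77
  },
  {
   "covariate": "egfr",
   "transform": "identity",
   "center": 76.0,
   "coef": -0.01837
  },
  {
   "covariate": "map_mmHg",
   "transform": "identity",
   "center": 99.0,
   "coef": 0.01232
  },
  {
   "covariate": "age_years",
   "transform": "identity",
   "center": 22.0,
   "coef": 0.00517
  },
  {
   "covariate": "mest_m",
   "transform": "identity",
   "center": 0.508,
   "coef": 0.363
  },
  {
   "covariate": "mest_e",
   "transform": "identity",
   "center": 0.369,
   "coef": 0.154
  },
  {
   "covariate": "mest_s",
   "transform": "identity",
   "center": 0.759,
   "coef": 0.407
  },
  {
   "covariate": "mest_t",
   "transform": "eq:1",
   "center": 0.264,
   "coef": 0.869
  },
  {
   "covariate": "mest_t",
   "transform": "eq:2",
   "center": 0.087,
   "coef": 1.43
  },
  {
   "covariate": "rasb_use",
   "transform": "bool",
   "center": 0.337,
   "coef": -0.209
  },
  {
   "covariate": "is_use",
   "transform": "bool",
   "center": 0.078,
   "coef": -0.308
  },
  {
   "covariate": "race",
   "transform": "eq:japanese",
   "center": 0.0,
   "coef": 0.275
  },
  {
   "covariate": "race",
   "transform": "eq:other",
   "center": 0.0,
   "coef": 0.11
  }
 ],
 "baseline_survival": [
  [
   0,
   1.0
  ],
  [
   6,
   0.997352
  ],
  [
   12,
   0.990808
  ],
  [
   18,
   0.981024
  ],
  [
   24,
   0.968356
  ],
  [
   30,
   0.953086
  ],
  [
   36,
   0.935463
  ],
  [
   42,
   0.915717
  ],
  [
   48,
   0.89407
  ],
  [
   54,
   0.870738
  ],
  [
   60,
   0.84593
  ],
  [
   66,
   0.81985
  ],
  [
   72,
   0.792699
  ],
  [
   78,
   0.764668
  ],
  [
   84,
   0.735943
  ],
  [
   90,
   0.706704
  ],
  [
   96,
   0.67712
  ],
  [
   102,
   0.647353
  ],
  [
   108,
   0.617555
  ],
  [
   114,
   0.587868
  ],
  [
   120,
   0.558423
  ]
 ],
 "race_piecewise": {
  "race": "chinese",
  "cutpoint_months": 36.0,
  "beta_early": 0.55,
  "beta_late": 0.2
 }
}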