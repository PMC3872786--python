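{
  "version": "1.0",
  "note": "Published regression models for predicting human imageability judgments (1-7 scale) from co-occurrence-derived predictors. 'context_density': ARC + INV-NCOUNT only. 'eight_emotion': similarities to 8 emotion terms. 'full': 7 emotion terms + ARC + INV-NCOUNT + LENGTH + LNFREQUENCY.",
  "models": {
    "context_density": {
      "intercept": {"estimate": 2.26, "se": 0.81, "t": 2.80, "p": 0.005},
      "predictors": {
        "arc": {"estimate": 2.59, "se": 0.82, "t": 3.13, "p": 0.002},
        "inv_ncount": {"estimate": -0.64, "se": 0.06, "t": -9.93, "p": 2e-16}
      },
      "r2": 0.08,
      "n": 1848
    },
    "eight_emotion": {
      "intercept": {"estimate": 4.34, "se": 0.18, "t": 23.56, "p": 2e-16},
      "predictors": {
        "admirable": {"estimate": -11.46, "se": 1.67, "t": -6.87, "p": 8.96e-12},
        "arouse": {"estimate": -14.84, "se": 1.54, "t": -9.61, "p": 2e-16},
        "envious": {"estimate": -16.50, "se": 2.82, "t": -5.85, "p": 5.87e-09},
        "from": {"estimate": 7.45, "se": 0.99, "t": 7.55, "p": 7.08e-14},
        "good": {"estimate": -11.31, "se": 0.93, "t": -12.11, "p": 2e-16},
        "horny": {"estimate": 19.42, "se": 2.41, "t": 8.05, "p": 1.44e-15},
        "pleasure": {"estimate": 13.17, "se": 1.10, "t": 11.93, "p": 2e-16},
        "proud": {"estimate": 11.16, "se": 1.56, "t": 7.17, "p": 1.12e-12}
      },
      "r2": 0.31,
      "n": 1848
    },
    "full": {
      "intercept": {"estimate": 3.25, "se": 0.72, "t": 4.51, "p": 7.00e-06},
      "predictors": {
        "admirable": {"estimate": -14.72, "se": 1.51, "t": -9.75, "p": 2e-16},
        "arouse": {"estimate": -12.83, "se": 1.42, "t": -9.03, "p": 2e-16},
        "envious": {"estimate": -9.93, "se": 2.78, "t": -3.57, "p": 3.64e-04},
        "good": {"estimate": -9.00, "se": 0.82, "t": -11.02, "p": 2e-16},
        "horny": {"estimate": 17.92, "se": 2.33, "t": 7.70, "p": 2.18e-14},
        "pleasure": {"estimate": 11.49, "se": 1.08, "t": 10.65, "p": 2e-16},
        "proud": {"estimate": 7.47, "se": 1.55, "t": 4.84, "p": 1.44e-06},
        "arc": {"estimate": 1.91, "se": 0.71, "t": 2.69, "p": 7.18e-03},
        "inv_ncount": {"estimate": -0.32, "se": 0.06, "t": -5.27, "p": 1.55e-07},
        "length": {"estimate": 0.07, "se": 0.03, "t": 2.54, "p": 0.011123},
        "lnfrequency": {"estimate": 0.12, "se": 0.02, "t": 7.10, "p": 1.78e-12}
      },
      "r2": 0.36,
      "aic": 5032,
      "n": 1848
    }
  },
  "composite_dimensions": {
    "context": ["arc", "inv_ncount"],
    "emotionality": ["admirable", "arouse", "envious", "good", "horny", "pleasure", "proud"]
  }
}
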