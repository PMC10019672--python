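{
  "label": "Hadlock 1985 three-parameter formula (HC, AC, FL), log10 grams, biometry in cm",
  "provenance": "Hadlock FP et al., Am J Obstet Gynecol 1985;151:333-337 (HC/AC/FL model)",
  "scale": "log10_g",
  "units": "cm",
  "coefficients": {
    "intercept": 1.326,
    "hc": 0.0107,
    "ac": 0.0438,
    "fl": 0.158,
    "ac_fl": -0.00326
  }
}
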