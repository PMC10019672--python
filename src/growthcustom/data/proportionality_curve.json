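{
  "label": "Gardosi proportionality curve: percent of term weight as a cubic in gestational weeks, renormalized to 1.0 at 280 days",
  "provenance": "Gardosi J et al., Ultrasound Obstet Gynecol 1995;6:168-174 (proportionality equation)",
  "scale": "percent_of_term",
  "argument": "gestational_weeks",
  "coefficients": [299.1, -31.85, 1.094, -0.01055],
  "support_days": [168, 294]
}
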