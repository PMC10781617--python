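{
  "trait": "hair",
  "reference_category": "brown",
  "intercepts": {"blond": -0.50, "red": -3.00, "black": -0.80},
  "note": "Illustrative multinomial-logistic panel in the documented format; replace variant ids and coefficients with a published pigmentation panel for real predictions."
}
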