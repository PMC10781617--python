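{
  "trait": "eye",
  "reference_category": "brown",
  "intercepts": {"blue": 3.94, "intermediate": 0.65},
  "note": "Illustrative multinomial-logistic panel in the documented format; replace variant ids and coefficients with a published pigmentation panel for real predictions."
}
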