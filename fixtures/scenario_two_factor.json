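{
 "type": "risk_table",
 "outcome": "accident",
 "outcome_level": "yes",
 "scale_note": "delta scale: values are published worked-example increases in accident probability relative to the normal situation, which is entered as 0",
 "note": "Two-factor DUI/snow worked example. Encodes the published single-factor deltas (DUI 0.895, snow 0.018) and combined delta (0.997) directly; because the baseline is entered as zero, table lookups reproduce those deltas exactly.",
 "factors": [
  {"variable": "physical_condition", "reference": "normal", "risk": "dui"},
  {"variable": "surface", "reference": "dry", "risk": "snow"}
 ],
 "values": [
  {"config": {"physical_condition": "normal", "surface": "dry"}, "risk": 0.0},
  {"config": {"physical_condition": "dui", "surface": "dry"}, "risk": 0.895},
  {"config": {"physical_condition": "normal", "surface": "snow"}, "risk": 0.018},
  {"config": {"physical_condition": "dui", "surface": "snow"}, "risk": 0.997}
 ]
}
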