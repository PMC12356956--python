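{
 "type": "risk_table",
 "outcome": "severity",
 "outcome_level": "fatal",
 "scale_note": "percentage-scale fatal-accident risk values as published (several exceed 1); gamma is scale-invariant",
 "note": "Three-factor DUI/snow/no-seatbelt worked example: published fatal-risk values for the baseline, each single-risk configuration, the all-risk configuration, and the DUI+snow-with-belt configuration.",
 "factors": [
  {"variable": "physical_condition", "reference": "normal", "risk": "dui"},
  {"variable": "surface", "reference": "dry", "risk": "snow"},
  {"variable": "safety_equipment", "reference": "belt", "risk": "none"}
 ],
 "values": [
  {"config": {"physical_condition": "normal", "surface": "dry", "safety_equipment": "belt"}, "risk": 0.259},
  {"config": {"physical_condition": "dui", "surface": "dry", "safety_equipment": "belt"}, "risk": 0.277},
  {"config": {"physical_condition": "normal", "surface": "snow", "safety_equipment": "belt"}, "risk": 0.273},
  {"config": {"physical_condition": "normal", "surface": "dry", "safety_equipment": "none"}, "risk": 4.793},
  {"config": {"physical_condition": "dui", "surface": "snow", "safety_equipment": "none"}, "risk": 5.193},
  {"config": {"physical_condition": "dui", "surface": "snow", "safety_equipment": "belt"}, "risk": 0.297}
 ]
}
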