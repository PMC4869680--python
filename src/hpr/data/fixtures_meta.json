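{
 "early_response_synthetic.tsv": {
  "kind": "early",
  "provenance": "synthetic stand-in generated by hpr.synthetic.fixture_curve",
  "norm": "peak absolute value = 1",
  "fs": 10.0,
  "duration_s": 11.0
 },
 "cs_minus_baseline_synthetic.tsv": {
  "kind": "cs_minus_baseline",
  "provenance": "synthetic stand-in generated by hpr.synthetic.fixture_curve",
  "norm": "peak absolute value = 1",
  "fs": 10.0,
  "duration_s": 11.0
 },
 "brief_stimulus_rf_synthetic.tsv": {
  "kind": "brief_stimulus",
  "provenance": "synthetic stand-in generated by hpr.synthetic.fixture_curve",
  "norm": "peak absolute value = 1",
  "fs": 10.0,
  "duration_s": 11.0
 }
}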