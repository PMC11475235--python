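{
  "library_total": 351,
  "previously_characterized": 6,
  "stage1_clusters": 93,
  "families": 44,
  "promoter_predicted_families": 26,
  "promoter_unpredictable_families": 18,
  "validated_active": 8
}
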