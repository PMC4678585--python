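# Synthetic placeholder unit-cost table (2012-13 GBP price-year layout).
# The analysis consumed national reference costs, NHS Blood and Transplant and
# BNF unit costs that are not redistributable here; these values are plausible
# placeholders for testing and worked examples and should be replaced with a
# user-supplied table for any real costing exercise.
price_year: "2012-13 (synthetic placeholder)"
ward_day: 300.0
cc_level2_day: 850.0
cc_level3_day: 1250.0
recovery_day: 400.0
monitor_per_patient: 200.0
dopexamine_per_mg: 1.60
crystalloid_per_ml: 0.001
colloid_per_ml: 0.010
blood_per_ml: 0.15
nurse_hour: 40.0
reference_cost:
  upper_GI: 7200.0
  lower_GI: 6100.0
  small_bowel_pancreas: 8300.0
  uro_gynae: 6000.0
  none: 0.0
avg_los_days:
  upper_GI: 9.0
  lower_GI: 8.0
  small_bowel_pancreas: 11.0
  uro_gynae: 8.0
  none: 0.0
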