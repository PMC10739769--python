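# AHEI-2010 component definitions over the packaged GDQS-group taxonomy.
# Each component is scored by linear interpolation between its 0-point and
# 10-point anchors (servings/day unless g_per_serving is 1, then g/day),
# clipped to [0, 10]. The sodium component is scored from the 0-100 sodium
# screener as 10 * (1 - screener/100). Alcohol and trans fat are not
# derivable from group-level gram intakes and are omitted from this default
# config; add components here if those variables are available.
components:
  vegetables:
    groups: [dark_green_leafy_vegetables, cruciferous_vegetables,
             deep_orange_vegetables, other_vegetables]
    g_per_serving: 80
    anchor0: 0.0
    anchor10: 5.0
  fruit:
    groups: [citrus_fruits, deep_orange_fruits, other_fruits]
    g_per_serving: 120
    anchor0: 0.0
    anchor10: 4.0
  whole_grains:
    groups: [whole_grains]
    g_per_serving: 1
    anchor0: 0.0
    anchor10: 75.0
  nuts_legumes:
    groups: [nuts_seeds, legumes]
    g_per_serving: 50
    anchor0: 0.0
    anchor10: 1.0
  long_chain_fats:
    groups: [fish_shellfish]
    g_per_serving: 1
    anchor0: 0.0
    anchor10: 100.0
  polyunsaturated_fat:
    groups: [liquid_oils]
    g_per_serving: 1
    anchor0: 0.0
    anchor10: 10.0
  ssb_and_juice:
    groups: [sugar_sweetened_beverages, juice]
    g_per_serving: 240
    anchor0: 1.0
    anchor10: 0.0
  red_processed_meat:
    groups: [red_meat, processed_meat]
    g_per_serving: 100
    anchor0: 1.5
    anchor10: 0.0
  sweets:
    groups: [sweets_ice_cream]
    g_per_serving: 70
    anchor0: 1.0
    anchor10: 0.0
sodium_from_screener: true
allow_partial_total: false
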