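# Global Dietary Recommendations score: sentinel-food dichotomous scoring.
# A group counts as consumed if any member food has grams > 0 on the scoring
# day. Score = (# encouraged groups consumed) + (# limit groups NOT consumed).
# Mapped onto the packaged GDQS-group taxonomy; editable.
encouraged:
  - whole_grains
  - legumes
  - nuts_seeds
  - citrus_fruits
  - deep_orange_fruits
  - other_fruits
  - dark_green_leafy_vegetables
  - deep_orange_vegetables
  - other_vegetables
limit:
  - sugar_sweetened_beverages
  - sweets_ice_cream
  - juice
  - processed_meat
  - red_meat
  - purchased_deep_fried_foods
  - refined_grains_baked_goods
  - high_fat_dairy
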