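# Minimum Dietary Diversity - Women: the 10 food groups, mapped onto the
# packaged GDQS-group taxonomy. A group counts as consumed at >= 15 g;
# diversity is adequate at >= 5 of 10 groups.
threshold_g: 15.0
min_groups: 5
groups:
  grains_white_roots_tubers:
    [whole_grains, refined_grains_baked_goods, white_roots_tubers]
  pulses: [legumes]
  nuts_seeds: [nuts_seeds]
  dairy: [low_fat_dairy, high_fat_dairy]
  meat_poultry_fish:
    [fish_shellfish, poultry_game_meat, red_meat, processed_meat]
  eggs: [eggs]
  dark_green_leafy_vegetables: [dark_green_leafy_vegetables]
  other_vitamin_a_rich:
    [deep_orange_fruits, deep_orange_vegetables, deep_orange_tubers]
  other_vegetables: [cruciferous_vegetables, other_vegetables]
  other_fruits: [citrus_fruits, other_fruits]
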