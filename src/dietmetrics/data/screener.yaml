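# Sodium-intake screener: 12 salty-food-group frequency items plus 10
# salt-habit items, each answered on an ordinal 0..max_level scale.
# Score = 100 * sum(w_i * x_i) / sum(w_i * max_i), so the possible range is
# 0-100 by construction. Weights and levels are editable.
items:
  freq_fish_sauce:        {max_level: 4, weight: 1.0}
  freq_soy_sauce:         {max_level: 4, weight: 1.0}
  freq_salted_fish:       {max_level: 4, weight: 1.0}
  freq_salted_egg:        {max_level: 4, weight: 1.0}
  freq_fermented_foods:   {max_level: 4, weight: 1.0}
  freq_processed_meat:    {max_level: 4, weight: 1.0}
  freq_instant_noodles:   {max_level: 4, weight: 1.0}
  freq_canned_foods:      {max_level: 4, weight: 1.0}
  freq_salty_snacks:      {max_level: 4, weight: 1.0}
  freq_seasoning_powder:  {max_level: 4, weight: 1.0}
  freq_chili_paste:       {max_level: 4, weight: 1.0}
  freq_pickled_fruit_veg: {max_level: 4, weight: 1.0}
  habit_add_sauce_at_table:   {max_level: 3, weight: 1.0}
  habit_taste_before_salting: {max_level: 3, weight: 1.0}
  habit_salty_preference:     {max_level: 3, weight: 1.0}
  habit_restaurant_food:      {max_level: 3, weight: 1.0}
  habit_drink_soup_broth:     {max_level: 3, weight: 1.0}
  habit_dipping_sauces:       {max_level: 3, weight: 1.0}
  habit_choose_low_sodium:    {max_level: 3, weight: 1.0}
  habit_read_labels:          {max_level: 3, weight: 1.0}
  habit_processed_convenience: {max_level: 3, weight: 1.0}
  habit_seasoning_in_cooking: {max_level: 3, weight: 1.0}
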