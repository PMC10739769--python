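group_id,name,category,cutoff1,cutoff2,cutoff3,pts0,pts1,pts2,pts3
citrus_fruits,Citrus fruits,healthy,24,69,,0,1,2,
deep_orange_fruits,Deep orange fruits,healthy,25,123,,0,1,2,
other_fruits,Other fruits,healthy,27,107,,0,1,2,
dark_green_leafy_vegetables,Dark green leafy vegetables,healthy,13,37,,0,1,2,
cruciferous_vegetables,Cruciferous vegetables,healthy,13,36,,0,1,2,
deep_orange_vegetables,Deep orange vegetables,healthy,9,45,,0,1,2,
other_vegetables,Other vegetables,healthy,23,114,,0,1,2,
legumes,Legumes,healthy,9,42,,0,1,2,
deep_orange_tubers,Deep orange tubers,healthy,12,63,,0,1,2,
nuts_seeds,Nuts and seeds,healthy,7,13,,0,1,2,
whole_grains,Whole grains,healthy,8,13,,0,1,2,
liquid_oils,Liquid oils,healthy,2,7.5,,0,1,2,
fish_shellfish,Fish and shellfish,healthy,14,71,,0,1,2,
poultry_game_meat,Poultry and game meat,healthy,16,44,,0,1,2,
low_fat_dairy,Low-fat dairy,healthy,33,132,,0,1,2,
eggs,Eggs,healthy,6,32,,0,1,2,
white_roots_tubers,White roots and tubers,unhealthy,12,56,,2,1,0,
processed_meat,Processed meat,unhealthy,9,30,,2,1,0,
refined_grains_baked_goods,Refined grains and baked goods,unhealthy,7,33,,2,1,0,
sweets_ice_cream,Sweets and ice cream,unhealthy,13,37,,2,1,0,
sugar_sweetened_beverages,Sugar-sweetened beverages,unhealthy,57,180,,2,1,0,
juice,Juice,unhealthy,36,144,,2,1,0,
purchased_deep_fried_foods,Purchased deep-fried foods,unhealthy,9,45,,2,1,0,
red_meat,Red meat,unhealthy_in_excess,9,46,,0,1,0,
high_fat_dairy,High-fat dairy,unhealthy_in_excess,35,142,734,0,1,2,0
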