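# Reference-cube portion model for app-style group-level portion estimation.
# Ten stackable cubes of predefined volume; a reported portion is any multiset
# of cubes with each cube used at most max_multiplicity times. Densities map
# cube volume (mL) to grams per food group. The published cube geometry is not
# public; these defaults are editable and carry no claim of matching the
# fielded instrument.
volumes_ml: [5, 10, 20, 30, 50, 75, 100, 150, 200, 300]
max_multiplicity: 2
default_density_g_per_ml: 1.0
density_g_per_ml:
  liquid_oils: 0.92
  nuts_seeds: 0.55
  whole_grains: 0.85
  refined_grains_baked_goods: 0.80
  sugar_sweetened_beverages: 1.0
  juice: 1.0
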