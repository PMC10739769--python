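nutrient,ear,units,per_kg,cv,source
protein,0.66,g/kg/d,1,0.125,national_academy
vitamin_a,430,RAE/d,0,0.20,thai_dri
thiamine,0.9,mg/d,0,0.10,national_academy
vitamin_b12,2.0,ug/d,0,0.10,national_academy
calcium,860,mg/d,0,0.11,harmonized_efsa
iron,8.1,mg/d,0,0.30,thai_dri
zinc,5.4,mg/d,0,0.125,thai_dri
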