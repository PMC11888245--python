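{
  "description": "Published aggregate counts from a drift-tube IMS-MS screening campaign of a regulatory chemical standards library; used as input for campaign-level arithmetic (class totals, duplicate collapsing, detection rates).",
  "n_standards": 4685,
  "n_plate_duplicates": 3,
  "n_detected_unique": 2140,
  "n_library_ions": 3993,
  "class_counts": {
    "Natural Toxin": 6,
    "Disinfection By-Product": 14,
    "PFAS": 17,
    "PAH": 31,
    "Surfactant": 78,
    "Flame Retardant": 120,
    "Plastic": 154,
    "Color Dye": 172,
    "Cosmetic Ingredient": 360,
    "Pharmaceutical": 615,
    "Food Additive": 634,
    "Pesticide": 948,
    "Chemical Industrial": 1536
  },
  "mode_unique_chemicals": {
    "ESI+": 1324,
    "ESI-": 1146,
    "APCI+": 771
  },
  "mode_only_chemicals": {
    "ESI+": 426,
    "ESI-": 634,
    "APCI+": 52
  },
  "stability": {
    "n_with_data": 3659,
    "pct_detected_and_stable": 37.6,
    "pct_neither": 26.6
  }
}
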