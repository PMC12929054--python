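{
  "version": "grassaudit-default-2024-01",
  "reference_classes": [
    {"code": "G1", "label": "open grassland", "category": "grassland", "simplified": "grassland", "aliases": ["1"]},
    {"code": "G2", "label": "wooded grassland / savanna (<=75% woody cover)", "category": "grassland", "simplified": "grassland", "aliases": ["2"]},
    {"code": "G3", "label": "shrub-dominated grassland with grass understory", "category": "grassland", "simplified": "grassland", "aliases": ["3"]},
    {"code": "G4", "label": "tundra grassland", "category": "grassland", "simplified": "grassland", "aliases": ["4"]},
    {"code": "G5", "label": "planted pasture", "category": "grassland", "simplified": "grassland", "aliases": ["5"]},
    {"code": "G6", "label": "sparse / barren grassland (>=5% grass cover)", "category": "grassland", "simplified": "grassland", "aliases": ["6"]},
    {"code": "7", "label": "grassland, type unsure", "category": "grassland", "simplified": null, "aliases": []},
    {"code": "N1", "label": "forest (no grassland understory)", "category": "non-grassland", "simplified": "forest", "aliases": ["F"]},
    {"code": "N2", "label": "shrubland (no grassland understory)", "category": "non-grassland", "simplified": "shrubland", "aliases": ["S"]},
    {"code": "N3", "label": "cropland", "category": "non-grassland", "simplified": "cropland", "aliases": ["C"]},
    {"code": "N4", "label": "settlement", "category": "non-grassland", "simplified": "settlement", "aliases": ["E"]},
    {"code": "N5", "label": "artificial turf / lawn", "category": "non-grassland", "simplified": "settlement", "aliases": ["A"]},
    {"code": "N6", "label": "open water", "category": "non-grassland", "simplified": "water", "aliases": ["W"]},
    {"code": "N7", "label": "wetland", "category": "non-grassland", "simplified": "wetland", "aliases": ["T"]},
    {"code": "N8", "label": "barren (<5% grass cover)", "category": "non-grassland", "simplified": "barren", "aliases": ["B"]},
    {"code": "N9", "label": "permanent snow / ice", "category": "non-grassland", "simplified": "snow_ice", "aliases": ["I"]},
    {"code": "U", "label": "unfilled", "category": "excluded", "simplified": null, "aliases": []}
  ],
  "simplified_classes": ["grassland", "forest", "shrubland", "cropland", "settlement", "water", "wetland", "barren", "snow_ice"],
  "legends": [
    {
      "product_id": "wc",
      "version": "WorldCover v200 (2021)",
      "classes": ["tree_cover", "shrubland", "grassland", "cropland", "built_up", "bare_sparse", "snow_ice", "water", "wetland_herbaceous", "mangroves", "moss_lichen"],
      "harmonization": {
        "tree_cover": "forest",
        "shrubland": "shrubland",
        "grassland": "grassland",
        "cropland": "cropland",
        "built_up": "settlement",
        "bare_sparse": "barren",
        "snow_ice": "snow_ice",
        "water": "water",
        "wetland_herbaceous": "wetland",
        "mangroves": "forest",
        "moss_lichen": "grassland"
      },
      "grassland_tokens": ["grassland", "moss_lichen"],
      "ambiguous_tokens": ["moss_lichen"]
    },
    {
      "product_id": "lc",
      "version": "ESRI Land Cover 2020",
      "classes": ["water", "trees", "flooded_vegetation", "crops", "built_area", "bare_ground", "snow_ice", "clouds", "rangeland"],
      "harmonization": {
        "water": "water",
        "trees": "forest",
        "flooded_vegetation": "wetland",
        "crops": "cropland",
        "built_area": "settlement",
        "bare_ground": "barren",
        "snow_ice": "snow_ice",
        "clouds": "U",
        "rangeland": "grassland"
      },
      "grassland_tokens": ["rangeland"],
      "ambiguous_tokens": ["rangeland"]
    },
    {
      "product_id": "dw",
      "version": "Dynamic World 2020-2021 composite",
      "classes": ["water", "trees", "grass", "flooded_vegetation", "crops", "shrub_and_scrub", "built", "bare", "snow_and_ice"],
      "harmonization": {
        "water": "water",
        "trees": "forest",
        "grass": "grassland",
        "flooded_vegetation": "wetland",
        "crops": "cropland",
        "shrub_and_scrub": "shrubland",
        "built": "settlement",
        "bare": "barren",
        "snow_and_ice": "snow_ice"
      },
      "grassland_tokens": ["grass"],
      "ambiguous_tokens": []
    }
  ]
}
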