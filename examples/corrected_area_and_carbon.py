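"""Ratio-correct a product's global grassland area and propagate it to carbon.

Inputs are the published validation-sample counts: 281,735 of 387,600
annotated pixels are reference grassland, and the best product (WC) labelled
240,266 of them correctly at 80.3% user's accuracy, which fixes the number of
sample pixels it called grassland.
"""

import grassaudit as ga

N_PIXELS = 387_600
N_REF_GRASS = 281_735
WC_CORRECT = 240_266
WC_USERS_ACCURACY = 0.803
WC_MAPPED_KM2 = 32.1e6
FAO_BASELINE_KM2 = 17.9e6

p_ref = N_REF_GRASS / N_PIXELS
p_map = (WC_CORRECT / WC_USERS_ACCURACY) / N_PIXELS

est = ga.corrected_area(WC_MAPPED_KM2, p_ref, p_map, product_id="wc")
print(f"reference grassland proportion: {est.p_ref:.3f}")
print(f"map grassland proportion:       {est.p_map:.3f}")
print(f"corrected area: {est.corrected_area_km2 / 1e6:.1f} million km^2 "
      f"({est.coverage_pct:.1f}% of the ice-free land surface)")

scenario = ga.carbon_scenario(est.corrected_area_km2, density_t_per_ha=51.5,
                              baseline_area_km2=FAO_BASELINE_KM2)
print(f"soil carbon stock (0-30 cm): {scenario.stock_pg:.2f} Pg C, "
      f"{scenario.pct_change:+.0f}% vs the 17.9 M km^2 baseline")

# The map overstates grassland in the validation sample (p_map > p_ref), so
# the correction shrinks the mapped 32.1 M km^2 to ~30.2 M km^2; at
# 51.5 t C/ha that area stores ~156 Pg of soil carbon, ~69% above the
# baseline inventory computed from the older, much smaller area estimate.
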