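"""Place the two-stage sampling frame around one site and export it.

Generates a true landscape, simulates the map product used for the 1/100
rule, snaps the core PSU grid to the 10-m covering grid, randomizes the 10
additional PSUs in the 5-km disc, and writes the grids as GeoJSON.
"""

import json

import numpy as np

import grassaudit as ga

rng = np.random.default_rng(21)
scheme = ga.default_scheme()
grid = ga.PixelGridSpec()

lon, lat = 17.5, 46.8
ccol, crow = grid.to_index(lon, lat)
half = 520  # cells; covers the 5-km disc plus a margin
landscape = ga.generate_landscape(
    ga.LandscapeSpec(n_cols=2 * half + 1, n_rows=2 * half + 1),
    rng, col0=ccol - half, row0=crow - half, grid=grid,
)
product = ga.generate_product_map(landscape, ga.default_error_models()["wc"], rng)
grass_mask = product.mask(scheme.legend("wc").grassland_tokens)

core = ga.make_psu_grid(lon, lat, site_id="demo", psu_index=0, grid=grid)
cfg = ga.SamplingConfig(radius_km=5.0, n_extra_psus=10, min_grassland_pixels=1)
extras = ga.sample_additional_psus(core, grass_mask, cfg, rng)

print(f"core PSU centroid: {core.centroid[1]:.5f}N {core.centroid[0]:.5f}E")
for g in extras:
    glon, glat = g.centroid
    d = ga.great_circle_km(lat, lon, glat, glon)
    n_grass = grass_mask.grassland_count(g.col0, g.row0)
    print(f"  PSU {g.psu_index:2d}: {d:4.2f} km from core, "
          f"{n_grass:3d}/100 map-grassland pixels")

geojson = ga.grids_to_geojson([core] + extras)
print(f"\nGeoJSON FeatureCollection with {len(geojson['features'])} PSU polygons")
print(json.dumps(geojson["features"][0]["properties"]))
# Every PSU lies within 5 km, contains at least one map-grassland pixel, and
# overlaps no other grid; placement is areally uniform over the disc.
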