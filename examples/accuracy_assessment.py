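"""Simulate a small validation study and score each product against it.

Builds binary confusion matrices (rows = map, columns = reference), then
prints user's / producer's / overall accuracy and Cohen's kappa per product.
"""

import grassaudit as ga

scheme = ga.default_scheme()
spec = ga.StudySpec(n_sites=10, psus_per_site=11)
bundle = ga.simulate_study(spec, seed=11, scheme=scheme)
print(f"{bundle.n_records} annotated pixels from {len(bundle.grids)} PSU grids\n")

for product in ("wc", "lc", "dw"):
    cm = ga.build_confusion(bundle.records, product, scheme, level="binary")
    ua = ga.users_accuracy(cm, "grassland")
    pa = ga.producers_accuracy(cm, "grassland")
    oa = ga.overall_accuracy(cm)
    kappa = ga.cohens_kappa(cm)
    print(f"{product.upper()}: grassland UA {100 * ua:5.1f}%  PA {100 * pa:5.1f}%  "
          f"overall {100 * oa:5.1f}%  kappa {kappa:.3f}")

# Producer's accuracy is the share of truly-grassland pixels the product
# finds (omission complement); user's accuracy is the share of its grassland
# labels that are right (commission complement).  The WC-like model finds
# most grassland but over-calls it on lawns and barren ground; the LC/DW-like
# models miss most grassland while rarely inventing it.

counts = ga.class_correct_counts(bundle.records, "wc", scheme)
print("\nWC correct/incorrect pixels per grassland class:")
print(counts.to_string())
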