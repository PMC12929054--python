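# grassaudit

Auditing high-resolution land-cover maps against expert grassland reference
annotations — and propagating what the audit finds into corrected global area
and soil-carbon estimates.

## The problem

Global 10-m land-cover products (ESA WorldCover, ESRI Land Cover, Google
Dynamic World) disagree wildly on how much of the Earth is grassland — their
mapped totals span roughly 3.5% to 24% of the ice-free land surface — largely
because grassland is hard to define (savanna? tundra? planted pasture?) and
hard to resolve spectrally.  Since grassland soils hold a large share of the
terrestrial carbon pool, this disagreement propagates directly into carbon
accounting.

`grassaudit` implements the audit pipeline for this problem, built for
researchers who validate land-cover maps against expert-annotated reference
pixels:

* a **reference classification** of 16 cover classes (7 grassland forms
  including the "known grassland, type unsure" code `7`, 9 non-grassland
  classes, plus the unfilled code `U`), with legend harmonization for each
  product into a shared simplified scheme and a binary grassland dichotomy;
* the **two-stage sampling design**: 100 m × 100 m primary sampling units
  (PSUs) of 100 individually annotated 10-m pixels (SSUs), snapped to a
  global covering grid — one core PSU per site plus 10 more randomized
  uniformly within a 5-km disc under a "≥ 1 map-grassland pixel in 100" rule
  and a no-overlap constraint;
* the **agreement engine**: confusion matrices (rows = map, columns =
  reference) at binary / simplified / full levels and PSU / location /
  overall scales, with user's accuracy UA_k = n_kk / n_k·, producer's
  accuracy PA_k = n_kk / n_·k, overall accuracy OA = tr(N)/n, and Cohen's
  κ = (p_o − p_e)/(1 − p_e);
* the **ratio-corrected area estimator**

      corrected area = mapped area × p_ref / p_map,

  where p_ref and p_map are the grassland proportions of the validation
  sample under the reference labels and the product labels respectively,
  with coverage expressed against the 131,319,290 km² ice-free land surface
  and carbon stocks computed as area × density (51.5 t C ha⁻¹ to 30 cm by
  default);
* a **nearest-neighbour dispersion audit** (Clark–Evans-style ratio and Z
  score, Monte-Carlo or closed-form null) for the site network;
* a **synthetic study generator** — patchy categorical landscapes, product
  maps drawn from class-conditional confusion models, annotation noise
  (`7` at 4% of grassland SSUs, rare `U`) — so the whole pipeline runs and
  is testable fully offline.

## Worked example

```bash
python examples/corrected_area_and_carbon.py
```

```
reference grassland proportion: 0.727
map grassland proportion:       0.772
corrected area: 30.2 million km^2 (23.0% of the ice-free land surface)
soil carbon stock (0-30 cm): 155.66 Pg C, +69% vs the 17.9 M km^2 baseline
```

Of 387,600 annotated validation pixels, 281,735 (72.7%) are reference
grassland while the best product labels 77.2% of the same sample grassland —
it over-calls grassland, so its mapped 32.1 million km² shrinks to
~30.2 million km² (23.0% coverage).  At 51.5 t C ha⁻¹ that area stores
~156 Pg of soil carbon, roughly 69% more than an inventory computed from the
older 17.9 million km² area estimate: the carbon answer is hostage to the
area estimate.

A simulated study shows the two error regimes the audit distinguishes
(`python examples/accuracy_assessment.py`):

```
WC: grassland UA  88.1%  PA  85.7%  overall  81.0%  kappa 0.523
LC: grassland UA  85.8%  PA  19.9%  overall  38.7%  kappa 0.064
DW: grassland UA  85.9%  PA  23.7%  overall  41.1%  kappa 0.079
```

The WC-like product finds most grassland (high producer's accuracy); the
LC/DW-like products miss most of it (omission error), which is what drives
their small mapped totals.  `examples/sampling_design.py` and
`examples/site_dispersion.py` demonstrate the sampling frame and the
dispersion audit.

There is also a thin CLI over the same functions:

```bash
grassaudit simulate --sites 10 --seed 1 --out records.csv
grassaudit assess --records records.csv --product wc --level binary
grassaudit carbon --area-km2 30.1e6 --density 51.5     # -> 155.02
```

## Layout

```
src/grassaudit/   scheme, sampling, agreement, estimation, synthetic, io, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   models, parameters, numerical choices, limitations
```
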