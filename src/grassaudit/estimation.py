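"""Global area correction and soil-carbon propagation.

A land-cover product maps some global grassland area; the validation sample
measures how that map over- or under-counts grassland.  The corrected global
area is the ratio estimate

    corrected area = mapped area x (p_ref / p_map)

where ``p_ref`` is the proportion of sampled pixels the reference
classification calls grassland and ``p_map`` the proportion the product calls
grassland over the same sample (common denominators cancel, so count ratios
may be supplied directly).  Coverage percentages are expressed against the
ice-free terrestrial surface (131,319,290 km² by default, overridable), and
corrected areas propagate to soil organic carbon stocks through a per-area
density (t C ha⁻¹, 0-30 cm depth for the default 51.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

#: ice-free terrestrial surface used as the coverage denominator, km²
LAND_SURFACE_KM2 = 131_319_290.0

#: soil organic carbon density for grassland to 30 cm depth, t C per hectare
DEFAULT_CARBON_DENSITY_T_PER_HA = 51.5

HA_PER_KM2 = 100.0
TONNES_PER_PG = 1e9


@dataclass(frozen=True)
class AreaEstimate:
    """Ratio-corrected grassland area for one product, with audit inputs."""

    product_id: str
    mapped_area_km2: float
    p_ref: float
    p_map: float
    corrected_area_km2: float
    coverage_pct: float
    land_surface_km2: float = LAND_SURFACE_KM2


@dataclass(frozen=True)
class CarbonScenario:
    """Area x density -> carbon stock, with optional baseline comparison."""

    area_km2: float
    density_t_per_ha: float
    stock_pg: float
    baseline_pg: float | None = None
    pct_change: float | None = None


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, as printed values are rounded.

    Works on the shortest decimal representation of ``x`` so that e.g. a stock
    of 155.015 Pg reports as 155.02 rather than drifting down through binary
    floating point.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def area_from_pixel_count(count: int, cell_size_m: float) -> float:
    """Pixel count at a given cell size -> km²."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if cell_size_m <= 0:
        raise ValueError("cell size must be positive")
    return count * cell_size_m**2 / 1e6


def corrected_area(
    mapped_area_km2: float,
    p_ref: float,
    p_map: float,
    product_id: str = "",
    land_surface_km2: float = LAND_SURFACE_KM2,
) -> AreaEstimate:
    """Apply the ratio correction and express coverage of the land surface."""
    if p_map <= 0:
        raise ValueError("map proportion must be positive")
    corrected = mapped_area_km2 * p_ref / p_map
    return AreaEstimate(
        product_id=product_id,
        mapped_area_km2=mapped_area_km2,
        p_ref=p_ref,
        p_map=p_map,
        corrected_area_km2=corrected,
        coverage_pct=coverage_percent(corrected, land_surface_km2),
        land_surface_km2=land_surface_km2,
    )


def proportions_from_records(records, product: str, scheme) -> tuple[float, float]:
    """(p_ref, p_map) over one annotated sample.

    Both proportions share the full record count as denominator (unfilled
    cells count toward neither class), mirroring the validation arithmetic
    where the ratio reduces to reference-grassland count over map-grassland
    count.
    """
    from .agreement import GRASSLAND, _map_labels, _ref_labels

    n = len(records)
    if n == 0:
        raise ValueError("no records")
    ref = _ref_labels(records["ref_code"], scheme, "binary")
    mp = _map_labels(records[product], scheme, product, "binary")
    return float((ref == GRASSLAND).sum()) / n, float((mp == GRASSLAND).sum()) / n


def coverage_percent(area_km2: float, land_surface_km2: float = LAND_SURFACE_KM2) -> float:
    """Share of the ice-free terrestrial surface, percent."""
    if land_surface_km2 <= 0:
        raise ValueError("land surface must be positive")
    return 100.0 * area_km2 / land_surface_km2


def area_from_coverage(coverage_pct: float, land_surface_km2: float = LAND_SURFACE_KM2) -> float:
    """Inverse of :func:`coverage_percent`."""
    return coverage_pct / 100.0 * land_surface_km2


def area_gap(a1_km2: float, a2_km2: float) -> float:
    """Absolute difference between two area estimates, km²."""
    return abs(a1_km2 - a2_km2)


def carbon_stock(
    area_km2: float,
    density_t_per_ha: float = DEFAULT_CARBON_DENSITY_T_PER_HA,
) -> float:
    """Soil carbon stock in Pg C (= billion tonnes) for an area and density."""
    if area_km2 < 0 or density_t_per_ha < 0:
        raise ValueError("area and density must be non-negative")
    return area_km2 * HA_PER_KM2 * density_t_per_ha / TONNES_PER_PG


def percent_change(new: float, baseline: float) -> float:
    """Relative change of ``new`` vs ``baseline``, percent."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (new - baseline) / baseline


def pool_share(pool_pg: float, total_pg: float) -> float:
    """One carbon pool's share of a total pool, percent."""
    if total_pg <= 0:
        raise ValueError("total must be positive")
    return 100.0 * pool_pg / total_pg


def carbon_scenario(
    area_km2: float,
    density_t_per_ha: float = DEFAULT_CARBON_DENSITY_T_PER_HA,
    baseline_area_km2: float | None = None,
) -> CarbonScenario:
    """Carbon stock for an area, optionally compared against a baseline area."""
    stock = carbon_stock(area_km2, density_t_per_ha)
    if baseline_area_km2 is None:
        return CarbonScenario(area_km2, density_t_per_ha, stock)
    baseline = carbon_stock(baseline_area_km2, density_t_per_ha)
    return CarbonScenario(
        area_km2=area_km2,
        density_t_per_ha=density_t_per_ha,
        stock_pg=stock,
        baseline_pg=baseline,
        pct_change=percent_change(stock, baseline),
    )
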