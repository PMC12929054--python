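"""Synthetic study generator.

Emulates the full validation study offline: a true cover-class landscape per
site (categorical raster on the 10-m covering grid, spatially patchy), land
cover product maps drawn from class-conditional confusion models, a core PSU
at a grassland pixel plus additional PSUs randomized within the site disc
under the 1/100 map-grassland rule, and expert annotation sheets carrying the
study's special codes ("7" = grassland, type unsure, at ~4% of grassland
SSUs; "U" = unfilled).

Every generator is a pure function of (spec, rng): identical outputs for
identical seeds.  Records carry a hidden ``true_class`` column for oracle
checks in tests — estimators never consume it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

from .sampling import (
    CELL_KEYS,
    PixelGridSpec,
    PSUGrid,
    SamplingConfig,
    make_psu_grid,
    sample_additional_psus,
)
from .scheme import GRASSLAND, UNFILLED_CODE, UNSURE_CODE, ClassificationScheme, default_scheme

#: default true-class mix: 27% non-grassland, planted-pasture share of
#: grassland near 9% and wooded grassland near 11% — the composition the
#: validation sample reports.  Note the grassland-targeted design (core PSU at
#: a grassland pixel, 1/100 rule) samples slightly more grassland than the
#: landscape prevalence, so annotated records run ~1-2 points below 27%.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "G1": 0.368,  # open grassland
    "G2": 0.078,  # wooded grassland / savanna
    "G3": 0.050,
    "G4": 0.120,  # tundra
    "G5": 0.066,  # planted pasture
    "G6": 0.048,
    "N1": 0.060,  # forest
    "N2": 0.030,
    "N3": 0.050,  # cropland
    "N4": 0.015,
    "N5": 0.045,  # artificial / lawn
    "N6": 0.020,
    "N7": 0.020,
    "N8": 0.025,
    "N9": 0.005,
}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class Raster:
    """Categorical raster on the covering grid, plain array + anchor indices.

    ``data[r, c]`` is an index into ``classes`` for the pixel at global
    covering-grid position ``(col0 + c, row0 + r)`` (row 0 is the southmost).
    """

    classes: tuple[str, ...]
    data: np.ndarray  # int16 (n_rows, n_cols)
    col0: int
    row0: int
    grid: PixelGridSpec = field(default_factory=PixelGridSpec)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def covers(self, col: int, row: int) -> bool:
        return (
            self.col0 <= col < self.col0 + self.data.shape[1]
            and self.row0 <= row < self.row0 + self.data.shape[0]
        )

    def index_at(self, col: int, row: int) -> int:
        if not self.covers(col, row):
            raise SyntheticError(f"pixel ({col}, {row}) outside raster extent")
        return int(self.data[row - self.row0, col - self.col0])

    def token_at(self, col: int, row: int) -> str:
        return self.classes[self.index_at(col, row)]

    def tokens_at(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        c = np.asarray(cols) - self.col0
        r = np.asarray(rows) - self.row0
        if (c < 0).any() or (r < 0).any() or (c >= self.shape[1]).any() or (r >= self.shape[0]).any():
            raise SyntheticError("pixels outside raster extent")
        return np.asarray(self.classes, dtype=object)[self.data[r, c]]

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.data.ravel(), minlength=len(self.classes))
        return {tok: int(n) for tok, n in zip(self.classes, counts)}

    def mask(self, tokens: set[str] | frozenset[str]) -> "BooleanMask":
        idx = np.array([i for i, t in enumerate(self.classes) if t in tokens])
        data = np.isin(self.data, idx)
        return BooleanMask(data=data, col0=self.col0, row0=self.row0)


@dataclass(frozen=True)
class BooleanMask:
    """Boolean pixel mask; satisfies the sampler's GrasslandSource protocol."""

    data: np.ndarray
    col0: int
    row0: int

    def grassland_count(self, col0: int, row0: int) -> int:
        c, r = col0 - self.col0, row0 - self.row0
        if c < 0 or r < 0 or c + 10 > self.data.shape[1] or r + 10 > self.data.shape[0]:
            return 0  # blocks beyond the mapped extent cannot satisfy the rule
        return int(self.data[r : r + 10, c : c + 10].sum())


@dataclass(frozen=True)
class LandscapeSpec:
    """True-landscape generator parameters.

    ``patchiness_cells`` is the spatial correlation length (Gaussian smoothing
    sigma) in 10-m cells; 0 gives i.i.d. cells.  ``block_cells`` coarsens the
    noise field before thresholding (class patches have block-sized texture),
    which keeps paper-scale landscapes cheap.
    """

    n_cols: int
    n_rows: int
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    patchiness_cells: float = 40.0
    block_cells: int = 5

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise SyntheticError("degenerate extent")
        if self.patchiness_cells < 0:
            raise SyntheticError("patchiness must be non-negative")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SyntheticError(f"class mix must sum to 1, got {total}")


@dataclass(frozen=True)
class ProductErrorModel:
    """Class-conditional label distribution: true class -> product tokens."""

    product_id: str
    rows: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for code, row in self.rows.items():
            s = sum(row.values())
            if not math.isclose(s, 1.0, abs_tol=1e-9):
                raise SyntheticError(f"row for {code!r} sums to {s}, not 1")
            if any(p < 0 for p in row.values()):
                raise SyntheticError(f"negative probability in row {code!r}")

    def sample(self, true_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one product token per input true class code."""
        true_codes = np.asarray(true_codes, dtype=object)
        out = np.empty(true_codes.shape, dtype=object)
        for code in pd.unique(true_codes):
            if code not in self.rows:
                raise SyntheticError(f"error model {self.product_id!r} has no row for {code!r}")
            sel = true_codes == code
            toks = list(self.rows[code])
            cum = np.cumsum([self.rows[code][t] for t in toks])
            u = rng.random(int(sel.sum()))
            out[sel] = np.asarray(toks, dtype=object)[np.searchsorted(cum, u)]
        return out

    def grassland_probability(self, legend) -> dict[str, float]:
        """P(product labels grassland | true class), per true class."""
        return {
            code: sum(p for tok, p in row.items() if legend.is_grassland_token(tok))
            for code, row in self.rows.items()
        }


@dataclass(frozen=True)
class AnnotationNoise:
    """Expert annotation imperfections applied to true classes."""

    unfilled_rate: float = 0.0005  # any cell -> "U"
    unsure_rate: float = 0.04  # grassland cell -> "7"

    def __post_init__(self) -> None:
        for r in (self.unfilled_rate, self.unsure_rate):
            if not 0 <= r <= 1:
                raise SyntheticError("noise rates must be in [0, 1]")


def generate_landscape(
    spec: LandscapeSpec,
    rng: np.random.Generator,
    col0: int = 0,
    row0: int = 0,
    grid: PixelGridSpec | None = None,
) -> Raster:
    """Generate a true-class raster whose proportions converge to the mix.

    Spatial structure comes from thresholding a Gaussian-smoothed noise field:
    the field is rank-normalized through the normal CDF into an approximately
    uniform surface, then cut at the cumulative class proportions, so patch
    size follows ``patchiness_cells`` while marginal class shares follow
    ``class_mix``.
    """
    classes = tuple(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    if spec.patchiness_cells == 0:
        u = rng.random((spec.n_rows, spec.n_cols))
    else:
        b = max(1, int(spec.block_cells))
        coarse = (math.ceil(spec.n_rows / b), math.ceil(spec.n_cols / b))
        # periodic smoothing keeps the field stationary: reflective padding
        # would deflate variance near edges and skew class shares spatially
        field_ = gaussian_filter(
            rng.standard_normal(coarse), sigma=spec.patchiness_cells / b, mode="wrap"
        )
        z = (field_ - field_.mean()) / max(field_.std(), 1e-12)
        u = np.repeat(np.repeat(ndtr(z), b, axis=0), b, axis=1)[: spec.n_rows, : spec.n_cols]
    data = np.searchsorted(cum, u, side="right").astype(np.int16)
    np.clip(data, 0, len(classes) - 1, out=data)
    return Raster(classes=classes, data=data, col0=col0, row0=row0,
                  grid=grid or PixelGridSpec())


def generate_product_map(
    truth: Raster, em: ProductErrorModel, rng: np.random.Generator
) -> Raster:
    """Draw a full product-token raster from the truth raster and error model."""
    tokens: list[str] = []
    for row in em.rows.values():
        for tok in row:
            if tok not in tokens:
                tokens.append(tok)
    tok_index = {t: i for i, t in enumerate(tokens)}
    out = np.empty(truth.data.shape, dtype=np.int16)
    u = rng.random(truth.data.shape)
    for ci, code in enumerate(truth.classes):
        sel = truth.data == ci
        if not sel.any():
            continue
        if code not in em.rows:
            raise SyntheticError(f"error model {em.product_id!r} has no row for {code!r}")
        row = em.rows[code]
        toks = list(row)
        cum = np.cumsum([row[t] for t in toks])
        drawn = np.searchsorted(cum, u[sel])
        out[sel] = np.asarray([tok_index[t] for t in toks], dtype=np.int16)[drawn]
    return Raster(classes=tuple(tokens), data=out, col0=truth.col0, row0=truth.row0,
                  grid=truth.grid)


def generate_annotations(
    truth: Raster,
    grids: Sequence[PSUGrid],
    noise: AnnotationNoise,
    rng: np.random.Generator,
    scheme: ClassificationScheme | None = None,
) -> pd.DataFrame:
    """One annotation record per SSU cell of each grid.

    Columns: site_id, psu, cell, ref_code, true_class.  Grassland cells flip
    to "7" with ``unsure_rate``; any cell becomes "U" with ``unfilled_rate``.
    """
    scheme = scheme or default_scheme()
    grass = {rc.code for rc in scheme.reference_classes if rc.category == GRASSLAND}
    frames = []
    for g in grids:
        cells = g.cells()
        cols = np.array([c for c, _ in cells.values()])
        rows = np.array([r for _, r in cells.values()])
        true = truth.tokens_at(cols, rows)
        ref = true.copy()
        is_grass = np.isin(true, list(grass))
        unsure = rng.random(len(ref)) < noise.unsure_rate
        ref[is_grass & unsure] = UNSURE_CODE
        unfilled = rng.random(len(ref)) < noise.unfilled_rate
        ref[unfilled] = UNFILLED_CODE
        frames.append(
            pd.DataFrame(
                {
                    "site_id": g.site_id,
                    "psu": g.psu_index,
                    "cell": list(cells),
                    "ref_code": ref,
                    "true_class": true,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# default product error models


def _grass_row(sens: float, miss: dict[str, float], grass_token: str) -> dict[str, float]:
    row = {grass_token: sens}
    rest = 1.0 - sens
    for tok, w in miss.items():
        row[tok] = row.get(tok, 0.0) + rest * w
    return row


def _nongrass_row(correct_token: str, fp: float, grass_token: str) -> dict[str, float]:
    return {correct_token: 1.0 - fp, grass_token: fp}


def default_error_models() -> dict[str, ProductErrorModel]:
    """WC-like (high grassland sensitivity, weak specificity) and LC/DW-like
    (low sensitivity, strong specificity) confusion models.

    Only a few rates are anchored to published per-class behaviour (wooded
    grassland found 65% of the time by the best product; lawns mislabelled
    grassland 59% of the time); the rest are plausible stand-ins chosen to
    reproduce the products' aggregate binary accuracies under the default
    class mix.
    """
    wc_sens = {"G1": 0.92, "G2": 0.65, "G3": 0.80, "G4": 0.90, "G5": 0.85, "G6": 0.75}
    wc_miss = {
        "G1": {"cropland": 0.5, "bare_sparse": 0.3, "shrubland": 0.2},
        "G2": {"tree_cover": 0.7, "shrubland": 0.3},
        "G3": {"shrubland": 0.8, "bare_sparse": 0.2},
        "G4": {"bare_sparse": 0.5, "snow_ice": 0.2, "shrubland": 0.3},
        "G5": {"cropland": 0.8, "built_up": 0.2},
        "G6": {"bare_sparse": 0.9, "shrubland": 0.1},
    }
    wc_fp = {"N1": 0.10, "N2": 0.40, "N3": 0.35, "N4": 0.20, "N5": 0.59,
             "N6": 0.02, "N7": 0.40, "N8": 0.45, "N9": 0.05}
    wc_correct = {"N1": "tree_cover", "N2": "shrubland", "N3": "cropland",
                  "N4": "built_up", "N5": "built_up", "N6": "water",
                  "N7": "wetland_herbaceous", "N8": "bare_sparse", "N9": "snow_ice"}
    wc_rows = {c: _grass_row(wc_sens[c], wc_miss[c], "grassland") for c in wc_sens}
    wc_rows.update({c: _nongrass_row(wc_correct[c], wc_fp[c], "grassland") for c in wc_fp})

    lc_sens = {"G1": 0.17, "G2": 0.08, "G3": 0.25, "G4": 0.22, "G5": 0.70, "G6": 0.10}
    lc_miss = {
        "G1": {"crops": 0.4, "bare_ground": 0.4, "trees": 0.2},
        "G2": {"trees": 0.9, "bare_ground": 0.1},
        "G3": {"trees": 0.5, "bare_ground": 0.5},
        "G4": {"bare_ground": 0.7, "snow_ice": 0.3},
        "G5": {"crops": 1.0},
        "G6": {"bare_ground": 1.0},
    }
    lc_fp = {"N1": 0.02, "N2": 0.30, "N3": 0.05, "N4": 0.05, "N5": 0.15,
             "N6": 0.01, "N7": 0.05, "N8": 0.15, "N9": 0.02}
    lc_correct = {"N1": "trees", "N2": "trees", "N3": "crops", "N4": "built_area",
                  "N5": "built_area", "N6": "water", "N7": "flooded_vegetation",
                  "N8": "bare_ground", "N9": "snow_ice"}
    lc_rows = {c: _grass_row(lc_sens[c], lc_miss[c], "rangeland") for c in lc_sens}
    lc_rows.update({c: _nongrass_row(lc_correct[c], lc_fp[c], "rangeland") for c in lc_fp})

    dw_sens = {"G1": 0.22, "G2": 0.10, "G3": 0.28, "G4": 0.25, "G5": 0.75, "G6": 0.12}
    dw_miss = {
        "G1": {"crops": 0.4, "bare": 0.3, "shrub_and_scrub": 0.3},
        "G2": {"trees": 0.8, "shrub_and_scrub": 0.2},
        "G3": {"shrub_and_scrub": 1.0},
        "G4": {"bare": 0.6, "snow_and_ice": 0.2, "shrub_and_scrub": 0.2},
        "G5": {"crops": 1.0},
        "G6": {"bare": 1.0},
    }
    dw_fp = {"N1": 0.02, "N2": 0.25, "N3": 0.06, "N4": 0.05, "N5": 0.20,
             "N6": 0.01, "N7": 0.05, "N8": 0.15, "N9": 0.02}
    dw_correct = {"N1": "trees", "N2": "shrub_and_scrub", "N3": "crops",
                  "N4": "built", "N5": "built", "N6": "water",
                  "N7": "flooded_vegetation", "N8": "bare", "N9": "snow_and_ice"}
    dw_rows = {c: _grass_row(dw_sens[c], dw_miss[c], "grass") for c in dw_sens}
    dw_rows.update({c: _nongrass_row(dw_correct[c], dw_fp[c], "grass") for c in dw_fp})

    return {
        "wc": ProductErrorModel("wc", wc_rows),
        "lc": ProductErrorModel("lc", lc_rows),
        "dw": ProductErrorModel("dw", dw_rows),
    }


# --------------------------------------------------------------------------
# full-study simulation


def paper_psu_layout() -> list[int]:
    """PSUs per site for the documented study layout.

    340 sites carry the full design (core + 10 randomized grids); the five
    documented regional site clusterings (21 + 21 + 31 + 62 + 29 = 164 sites)
    contribute a single core grid each, giving 3,904 grids / 390,400 pixels —
    within 1% of the published pixel total.
    """
    return [11] * 340 + [1] * 164


@dataclass(frozen=True)
class StudySpec:
    """Conditions of one simulated validation study (defaults = study design)."""

    n_sites: int = 504
    psus_per_site: int = 11
    psu_layout: tuple[int, ...] | None = None  # overrides psus_per_site when given
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    patchiness_cells: float = 40.0
    block_cells: int = 5
    noise: AnnotationNoise = field(default_factory=AnnotationNoise)
    products: tuple[str, ...] = ("wc", "lc", "dw")
    full_raster_products: tuple[str, ...] = ("wc",)
    core_at_grassland: bool = True
    lat_range: tuple[float, float] = (-55.0, 65.0)
    lon_range: tuple[float, float] = (-175.0, 175.0)

    def layout(self) -> list[int]:
        if self.psu_layout is not None:
            if len(self.psu_layout) != self.n_sites:
                raise SyntheticError("psu_layout length must equal n_sites")
            return list(self.psu_layout)
        return [self.psus_per_site] * self.n_sites


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    spec: StudySpec
    sites: pd.DataFrame  # site_id, lat, lon
    grids: list[PSUGrid]
    records: pd.DataFrame  # site_id, psu, cell, ref_code, <products...>, true_class
    true_grass_area_km2: float
    total_area_km2: float
    mapped_area_km2: dict[str, float]  # full-raster products only

    @property
    def n_records(self) -> int:
        return len(self.records)


def _nearest_true_grass(
    truth: Raster, grass_codes: set[str], center_col: int, center_row: int
) -> tuple[int, int]:
    """Grassland pixel nearest the landscape center (expanding window search)."""
    mask = truth.mask(frozenset(grass_codes))
    c0, r0 = center_col - truth.col0, center_row - truth.row0
    n_rows, n_cols = truth.shape
    for half in (8, 32, 128, max(n_rows, n_cols)):
        r_lo, r_hi = max(0, r0 - half), min(n_rows, r0 + half + 1)
        c_lo, c_hi = max(0, c0 - half), min(n_cols, c0 + half + 1)
        window = mask.data[r_lo:r_hi, c_lo:c_hi]
        if window.any():
            rr, cc = np.nonzero(window)
            d2 = (rr + r_lo - r0) ** 2 + (cc + c_lo - c0) ** 2
            k = int(np.argmin(d2))
            return int(cc[k] + c_lo + truth.col0), int(rr[k] + r_lo + truth.row0)
    raise SyntheticError("landscape contains no grassland pixel")


def simulate_study(
    spec: StudySpec | None = None,
    seed: int | np.random.Generator = 0,
    scheme: ClassificationScheme | None = None,
    error_models: Mapping[str, ProductErrorModel] | None = None,
) -> StudyBundle:
    """Simulate a complete validation study.

    For each site: draw a coordinate, generate the true landscape over the
    site disc, place the core PSU (at the grassland pixel nearest the site
    coordinate when ``core_at_grassland``), randomize the additional PSUs
    against the product named first in ``full_raster_products`` (the "1/100"
    product), annotate all SSU cells with noise, and attach product labels —
    full rasters for ``full_raster_products``, record-level conditional draws
    for the rest.
    """
    spec = spec or StudySpec()
    scheme = scheme or default_scheme()
    ems = dict(error_models or default_error_models())
    for p in spec.products:
        if p not in ems:
            raise SyntheticError(f"no error model for product {p!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = PixelGridSpec()
    grass_codes = {rc.code for rc in scheme.reference_classes if rc.category == GRASSLAND}
    rule_product = spec.full_raster_products[0]
    rule_legend = scheme.legend(rule_product)

    layout = spec.layout()
    km_ns = grid.cell_deg * (math.pi * 6371.0088 / 180.0)  # ~0.01 km per cell N-S

    site_rows = []
    all_grids: list[PSUGrid] = []
    record_frames: list[pd.DataFrame] = []
    true_grass_km2 = 0.0
    total_km2 = 0.0
    mapped_km2 = {p: 0.0 for p in spec.full_raster_products}

    for i, n_psus in enumerate(layout):
        site_id = f"S{i + 1:04d}"
        lat = rng.uniform(*spec.lat_range)
        lon = rng.uniform(*spec.lon_range)
        site_rows.append({"site_id": site_id, "lat": lat, "lon": lon})

        pad_km = spec.sampling.radius_km + 0.12
        half_rows = math.ceil(pad_km / km_ns)
        half_cols = math.ceil(pad_km / (km_ns * math.cos(math.radians(lat))))
        ccol, crow = grid.to_index(lon, lat)
        lspec = LandscapeSpec(
            n_cols=2 * half_cols + 1,
            n_rows=2 * half_rows + 1,
            class_mix=spec.class_mix,
            patchiness_cells=spec.patchiness_cells,
            block_cells=spec.block_cells,
        )
        truth = generate_landscape(lspec, rng, col0=ccol - half_cols,
                                   row0=crow - half_rows, grid=grid)

        cell_km2 = grid.cell_area_km2(crow)
        counts = truth.class_counts()
        n_cells = truth.data.size
        total_km2 += n_cells * cell_km2
        true_grass_km2 += sum(counts[c] for c in grass_codes if c in counts) * cell_km2

        full_rasters = {}
        for p in spec.full_raster_products:
            full_rasters[p] = generate_product_map(truth, ems[p], rng)
            legend = scheme.legend(p)
            pm = full_rasters[p].mask(legend.grassland_tokens)
            mapped_km2[p] += int(pm.data.sum()) * cell_km2

        if spec.core_at_grassland:
            core_col, core_row = _nearest_true_grass(truth, grass_codes, ccol, crow)
        else:
            core_col, core_row = ccol, crow
        core_lon, core_lat = grid.cell_center(core_col, core_row)
        core = make_psu_grid(core_lon, core_lat, site_id, psu_index=0, grid=grid)

        grids = [core]
        if n_psus > 1:
            cfg = dataclasses.replace(spec.sampling, n_extra_psus=n_psus - 1)
            rule_mask = full_rasters[rule_product].mask(rule_legend.grassland_tokens)
            grids += sample_additional_psus(core, rule_mask, cfg, rng)
        all_grids.extend(grids)

        recs = generate_annotations(truth, grids, spec.noise, rng, scheme)
        for p in spec.products:
            if p in full_rasters:
                cells = [g.cells() for g in grids]
                cols = np.array([c for cc in cells for c, _ in cc.values()])
                rows = np.array([r for cc in cells for _, r in cc.values()])
                recs[p] = full_rasters[p].tokens_at(cols, rows)
            else:
                recs[p] = ems[p].sample(recs["true_class"].to_numpy(), rng)
        record_frames.append(recs)

    records = pd.concat(record_frames, ignore_index=True)
    return StudyBundle(
        spec=spec,
        sites=pd.DataFrame(site_rows),
        grids=all_grids,
        records=records,
        true_grass_area_km2=true_grass_km2,
        total_area_km2=total_km2,
        mapped_area_km2=mapped_km2,
    )
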