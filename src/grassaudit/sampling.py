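"""Two-stage spatial sampling design and the site-dispersion audit.

A validation *site* consists of a core primary sampling unit (PSU) — a
100 m x 100 m grid of 100 secondary sampling units (SSUs, 10 m x 10 m pixels)
placed at the provided research coordinate — plus up to 10 additional PSUs
randomized uniformly within a 5-km radius, each required to contain at least
one map-grassland pixel (the "1/100" rule) and to overlap no previously
accepted PSU (on overlap the most recently placed grid is re-randomized).

PSU grids snap to a fixed global covering grid of 10-m pixels expressed in
geographic degrees (cells are exactly 10 m north-south everywhere and
10·cos(lat) m east-west, mirroring how fixed-degree 10-m land-cover tiles
behave away from the equator).

The module also provides great-circle / geodesic distances and the
nearest-neighbour dispersion statistic (Clark–Evans-style ratio and Z score)
used to audit the spatial distribution of the site network.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088
_KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0  # ~111.195 km per degree of arc

# WGS84 ellipsoid
_WGS84_A = 6378.137
_WGS84_F = 1 / 298.257223563
_WGS84_B = _WGS84_A * (1 - _WGS84_F)

ROW_LETTERS = string.ascii_uppercase[:10]  # A (north) .. J (south)
CELL_KEYS = tuple(f"{r}{c}" for r in ROW_LETTERS for c in range(1, 11))


class SamplingError(RuntimeError):
    """Raised when PSU placement cannot satisfy its constraints."""


@dataclass(frozen=True)
class PixelGridSpec:
    """A global covering grid of ~10-m pixels in geographic degrees.

    Pixel (col, row) spans ``[origin + index*cell_deg, origin + (index+1)*cell_deg)``
    half-open in both axes; col counts east from origin_lon, row north from
    origin_lat.
    """

    origin_lon: float = -180.0
    origin_lat: float = -90.0
    cell_deg: float = 10.0 / 111_195.0  # 10 m of arc north-south

    def to_index(self, lon: float, lat: float) -> tuple[int, int]:
        col = math.floor((lon - self.origin_lon) / self.cell_deg)
        row = math.floor((lat - self.origin_lat) / self.cell_deg)
        return col, row

    def cell_bounds(self, col: int, row: int) -> tuple[float, float, float, float]:
        """(west, south, east, north) of a pixel footprint, degrees."""
        w = self.origin_lon + col * self.cell_deg
        s = self.origin_lat + row * self.cell_deg
        return w, s, w + self.cell_deg, s + self.cell_deg

    def cell_center(self, col: int, row: int) -> tuple[float, float]:
        w, s, e, n = self.cell_bounds(col, row)
        return (w + e) / 2.0, (s + n) / 2.0

    def cell_area_km2(self, row: int) -> float:
        """Approximate pixel area at this row's latitude."""
        _, lat = self.cell_center(0, row)
        ns_km = self.cell_deg * _KM_PER_DEG
        ew_km = ns_km * math.cos(math.radians(lat))
        return ns_km * ew_km


@dataclass(frozen=True)
class PSUGrid:
    """One 10x10 block of covering-grid pixels.

    ``col0``/``row0`` index the south-west pixel of the block.  Cell keys run
    A1 (north-west) to J10 ... row letters north->south, column numbers
    west->east.
    """

    site_id: str
    psu_index: int
    col0: int
    row0: int
    grid: PixelGridSpec = field(default_factory=PixelGridSpec)

    @property
    def centroid(self) -> tuple[float, float]:
        """(lon, lat) of the block center."""
        w, s, *_ = self.grid.cell_bounds(self.col0, self.row0)
        half = 5 * self.grid.cell_deg
        return w + half, s + half

    def cell_index(self, key: str) -> tuple[int, int]:
        """Global (col, row) pixel index of one cell key."""
        letter, num = key[0], int(key[1:])
        r = ROW_LETTERS.index(letter)  # 0 = north row
        return self.col0 + num - 1, self.row0 + 9 - r

    def cells(self) -> dict[str, tuple[int, int]]:
        return {k: self.cell_index(k) for k in CELL_KEYS}

    def cell_polygon(self, key: str) -> list[tuple[float, float]]:
        """Closed (lon, lat) ring of one cell footprint."""
        col, row = self.cell_index(key)
        w, s, e, n = self.grid.cell_bounds(col, row)
        return [(w, s), (e, s), (e, n), (w, n), (w, s)]

    def polygon(self) -> list[tuple[float, float]]:
        """Closed (lon, lat) ring of the whole PSU footprint."""
        w, s, *_ = self.grid.cell_bounds(self.col0, self.row0)
        e = w + 10 * self.grid.cell_deg
        n = s + 10 * self.grid.cell_deg
        return [(w, s), (e, s), (e, n), (w, n), (w, s)]

    def overlaps(self, other: "PSUGrid") -> bool:
        """Exact overlap test on snapped pixel-index ranges."""
        return (
            self.col0 < other.col0 + 10
            and other.col0 < self.col0 + 10
            and self.row0 < other.row0 + 10
            and other.row0 < self.row0 + 10
        )


@dataclass(frozen=True)
class SamplingConfig:
    """Parameters of the additional-PSU randomization."""

    radius_km: float = 5.0
    n_extra_psus: int = 10
    min_grassland_pixels: int = 1
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if not 0 <= self.min_grassland_pixels <= 100:
            raise ValueError("min_grassland_pixels must be in [0, 100]")


@dataclass(frozen=True)
class NNStats:
    """Nearest-neighbour dispersion summary for a point set."""

    n_points: int
    observed_mean_km: float
    expected_mean_km: float
    se_km: float
    z: float
    ratio: float


class GrasslandSource(Protocol):
    """Anything that can count map-grassland pixels in a 10x10 pixel block."""

    def grassland_count(self, col0: int, row0: int) -> int: ...


def make_psu_grid(
    lon: float,
    lat: float,
    site_id: str = "",
    psu_index: int = 0,
    grid: PixelGridSpec | None = None,
) -> PSUGrid:
    """Snap a centroid to the covering grid and build its 10x10 PSU block.

    The block is centered on the pixel containing the centroid, so any two
    centroids inside the same 10-m pixel yield the identical grid.
    """
    if not (-90.0 < lat < 90.0):
        raise ValueError(f"latitude {lat} at/beyond pole singularity")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon} out of range")
    grid = grid or PixelGridSpec()
    col, row = grid.to_index(lon, lat)
    return PSUGrid(site_id=site_id, psu_index=psu_index, col0=col - 4, row0=row - 4, grid=grid)


def _offset_point(lon: float, lat: float, east_km: float, north_km: float) -> tuple[float, float]:
    """Local tangent-plane offset, inverse-projected to lon/lat."""
    new_lat = lat + north_km / _KM_PER_DEG
    new_lon = lon + east_km / (_KM_PER_DEG * math.cos(math.radians(lat)))
    return new_lon, new_lat


def sample_additional_psus(
    core: PSUGrid,
    grassland_map: GrasslandSource,
    cfg: SamplingConfig,
    rng: np.random.Generator,
) -> list[PSUGrid]:
    """Randomize the additional PSUs around a core grid.

    Placement is areally uniform over the disc (r = R*sqrt(u), theta = 2*pi*u'
    on the local tangent plane).  Each accepted PSU lies within
    ``cfg.radius_km`` of the core centroid, contains at least
    ``cfg.min_grassland_pixels`` map-grassland pixels, and overlaps no
    previously accepted grid; the most recently drawn grid is re-randomized on
    any violation.
    """
    lon0, lat0 = core.centroid
    accepted: list[PSUGrid] = [core]
    out: list[PSUGrid] = []
    for k in range(cfg.n_extra_psus):
        reasons = {"radius": 0, "grassland": 0, "overlap": 0}
        for _ in range(cfg.max_attempts):
            r = cfg.radius_km * math.sqrt(rng.random())
            theta = 2 * math.pi * rng.random()
            lon, lat = _offset_point(lon0, lat0, r * math.sin(theta), r * math.cos(theta))
            cand = make_psu_grid(lon, lat, core.site_id, psu_index=k + 1, grid=core.grid)
            clon, clat = cand.centroid
            if great_circle_km(lat0, lon0, clat, clon) > cfg.radius_km:
                reasons["radius"] += 1
                continue
            if grassland_map.grassland_count(cand.col0, cand.row0) < cfg.min_grassland_pixels:
                reasons["grassland"] += 1
                continue
            if any(cand.overlaps(g) for g in accepted):
                reasons["overlap"] += 1
                continue
            accepted.append(cand)
            out.append(cand)
            break
        else:
            worst = max(reasons, key=reasons.get)
            raise SamplingError(
                f"no valid placement for PSU {k + 1} of site {core.site_id!r} after "
                f"{cfg.max_attempts} attempts (dominant failed constraint: {worst}, "
                f"rejections: {reasons})"
            )
    return out


# --------------------------------------------------------------------------
# distances


def great_circle_km(
    lat1: float, lon1: float, lat2: float, lon2: float, model: str = "sphere"
) -> float:
    """Shortest surface distance between two points, km.

    ``model="sphere"`` uses the haversine formula on a sphere of radius
    6371.0088 km (default); ``model="wgs84"`` uses Vincenty's inverse method
    on the WGS84 ellipsoid (falls back to the sphere for near-antipodal pairs
    where the iteration does not converge).
    """
    if model == "sphere":
        phi1, phi2 = math.radians(lat1), math.radians(lat2)
        dphi = phi2 - phi1
        dlam = math.radians(lon2 - lon1)
        a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
        return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))
    if model == "wgs84":
        return _vincenty_km(lat1, lon1, lat2, lon2)
    raise ValueError(f"unknown earth model {model!r}")


def _vincenty_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    U1 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat2)))
    L = math.radians(lon2 - lon1)
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        cos_2sm = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha else 0.0
        C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    else:
        # antipodal non-convergence: sphere is within 0.6% anyway
        return great_circle_km(lat1, lon1, lat2, lon2, model="sphere")
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    d_sigma = B * sin_sigma * (
        cos_2sm
        + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sm**2)
            - B / 6 * cos_2sm * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sm**2)
        )
    )
    return _WGS84_B * A * (sigma - d_sigma)


def disc_area_km2(radius_km: float) -> float:
    """Planar area of the randomization disc, km^2."""
    if radius_km < 0:
        raise ValueError("radius must be non-negative")
    return math.pi * radius_km**2


def _pairwise_nn_km(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Per-point distance to its nearest neighbour (haversine, vectorized)."""
    phi = np.radians(lats)[:, None]
    lam = np.radians(lons)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    a = np.sin(dphi / 2) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _sample_region(
    rng: np.random.Generator, n: int, region: tuple[float, float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """n points uniform by area on the sphere patch (lat_min, lat_max, lon_min, lon_max)."""
    lat_min, lat_max, lon_min, lon_max = region
    z = rng.uniform(math.sin(math.radians(lat_min)), math.sin(math.radians(lat_max)), n)
    lats = np.degrees(np.arcsin(z))
    lons = rng.uniform(lon_min, lon_max, n)
    return lats, lons


def sample_csr_points(
    n: int,
    region: tuple[float, float, float, float],
    rng: np.random.Generator | int | None = None,
) -> list[tuple[float, float]]:
    """n (lat, lon) points under complete spatial randomness over a bounding box."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lats, lons = _sample_region(gen, n, region)
    return list(zip(lats.tolist(), lons.tolist()))


def region_area_km2(region: tuple[float, float, float, float]) -> float:
    """Area of a lat/lon bounding box on the sphere, km^2."""
    lat_min, lat_max, lon_min, lon_max = region
    return (
        EARTH_RADIUS_KM**2
        * math.radians(lon_max - lon_min)
        * (math.sin(math.radians(lat_max)) - math.sin(math.radians(lat_min)))
    )


def nn_stats_from_summary(
    observed_mean_km: float,
    expected_mean_km: float,
    se_km: float,
    n_points: int = 0,
) -> NNStats:
    """Dispersion statistics from already-summarized distances.

    Used to audit published summaries where the per-site distances are not
    available: the ratio and Z score are recomputed from the printed observed
    mean, expected mean and standard error.
    """
    if expected_mean_km <= 0 or se_km <= 0:
        raise ValueError("expected mean and se must be positive")
    return NNStats(
        n_points=n_points,
        observed_mean_km=observed_mean_km,
        expected_mean_km=expected_mean_km,
        se_km=se_km,
        z=(observed_mean_km - expected_mean_km) / se_km,
        ratio=observed_mean_km / expected_mean_km,
    )


def nn_dispersion(
    points: Sequence[tuple[float, float]],
    expected_mean_km: float | None = None,
    se_km: float | None = None,
    region: tuple[float, float, float, float] | None = None,
    n_reps: int = 500,
    rng: np.random.Generator | int | None = None,
    expectation: str = "monte-carlo",
) -> NNStats:
    """Nearest-neighbour dispersion statistic for a set of (lat, lon) points.

    The observed statistic is the mean over points of the great-circle
    distance to the nearest other point.  The null expectation is either
    supplied directly (``expected_mean_km``, ``se_km`` — e.g. printed
    summaries being audited), or simulated by Monte-Carlo complete spatial
    randomness over a bounding-box ``region`` (default), or taken from the
    planar Clark–Evans closed form ``0.5/sqrt(n/A)`` with
    ``expectation="clark-evans"``.

    ``ratio > 1`` indicates dispersion (points further apart than random),
    ``ratio < 1`` clustering; ``z = (observed - expected) / se``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two (lat, lon) points")
    lats, lons = pts[:, 0], pts[:, 1]
    observed = float(_pairwise_nn_km(lats, lons).mean())
    n = len(pts)

    if expected_mean_km is None:
        if region is None:
            raise ValueError("supply expected_mean_km/se_km or a region for the null")
        if expectation == "clark-evans":
            area = region_area_km2(region)
            expected_mean_km = 0.5 / math.sqrt(n / area)
            if se_km is None:
                se_km = 0.26136 / math.sqrt(n**2 / area)
        elif expectation == "monte-carlo":
            gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
            means = np.empty(n_reps)
            for i in range(n_reps):
                rl, rn = _sample_region(gen, n, region)
                means[i] = _pairwise_nn_km(rl, rn).mean()
            expected_mean_km = float(means.mean())
            if se_km is None:
                se_km = float(means.std(ddof=1))
        else:
            raise ValueError(f"unknown expectation mode {expectation!r}")
    if se_km is None:
        raise ValueError("se_km required when expected_mean_km is supplied")

    ratio = observed / expected_mean_km if expected_mean_km > 0 else math.nan
    z = (observed - expected_mean_km) / se_km if se_km > 0 else math.nan
    return NNStats(
        n_points=n,
        observed_mean_km=observed,
        expected_mean_km=float(expected_mean_km),
        se_km=float(se_km),
        z=float(z),
        ratio=float(ratio),
    )
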