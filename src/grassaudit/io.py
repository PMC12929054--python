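"""Readers and writers for the on-disk formats.

Canonical interchange is delimited text plus JSON:

* pixel-record tables — CSV with header ``site_id,psu,cell,ref_code,<products...>``;
* annotation sheets — a 10x10 labelled block (header row ``,1..10``, row
  labels A..J), values cleaned through the scheme's annotation cleaner;
* site coordinates — CSV ``site_id,lat,lon`` in WGS84 decimal degrees;
* PSU grids — GeoJSON FeatureCollections of cell or grid polygons
  (coordinates are lon/lat; cell footprints are half-open on the covering
  grid, serialized as closed rings);
* rasters — a plain-matrix text format: a JSON header line prefixed ``#``
  carrying anchor indices and the class list, then one row of class indices
  per line, southmost row first;
* reports — versioned JSON with seed and config hash for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .sampling import CELL_KEYS, ROW_LETTERS, PixelGridSpec, PSUGrid
from .scheme import ClassificationScheme, default_scheme
from .synthetic import Raster


class FormatError(ValueError):
    pass


@dataclass
class AnnotationSheet:
    """One parsed and cleaned 10x10 annotation grid."""

    site_id: str
    psu_index: int
    cells: dict[str, str]  # A1..J10 -> reference code
    note: str = ""
    cleaning_log: list[str] = dataclasses.field(default_factory=list)


# --------------------------------------------------------------------------
# pixel-record tables


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "cell": str, "ref_code": str})
    required = {"site_id", "psu", "cell", "ref_code"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"record table missing columns: {sorted(missing)}")
    return df


def read_site_coords(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = {"site_id", "lat", "lon"} - set(df.columns)
    if missing:
        raise FormatError(f"coordinate table missing columns: {sorted(missing)}")
    return df


def write_site_coords(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, index=False)


# --------------------------------------------------------------------------
# annotation sheets


def read_annotation_sheet(
    path: str | Path,
    scheme: ClassificationScheme | None = None,
    site_id: str | None = None,
    psu_index: int = 0,
    context_rule: str = "majority",
) -> AnnotationSheet:
    """Parse one 10x10 annotation sheet and clean its codes.

    ``context_rule="majority"`` corrects unresolvable tokens toward the
    sheet's most frequent recognized entry (the "grid full of 1s with a stray
    12" case); pass ``None`` to disable context correction.
    """
    scheme = scheme or default_scheme()
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df.index = [str(i).strip().upper() for i in df.index]
    df.columns = [str(c).strip() for c in df.columns]
    missing_rows = [r for r in ROW_LETTERS if r not in df.index]
    missing_cols = [c for c in map(str, range(1, 11)) if c not in df.columns]
    if missing_rows or missing_cols:
        raise FormatError(
            f"{path.name}: malformed grid (missing rows {missing_rows}, "
            f"columns {missing_cols})"
        )

    raw = {f"{r}{c}": df.loc[r, str(c)] for r in ROW_LETTERS for c in range(1, 11)}
    majority = None
    if context_rule == "majority":
        recognized = [v.strip() for v in raw.values()
                      if v.strip() in scheme._alias_map]
        if recognized:
            majority = pd.Series(recognized).mode().iloc[0]
    log: list[str] = []
    cells: dict[str, str] = {}
    for key in CELL_KEYS:
        value = raw[key]
        if value is None or (not isinstance(value, str) and pd.isna(value)):
            raise FormatError(f"{path.name}: missing cell {key}")
        code, entry = scheme.clean_annotation(value, context_code=majority)
        cells[key] = code
        if entry:
            log.append(f"{key}: {entry}")
    if len(cells) != 100:
        missing = sorted(set(CELL_KEYS) - set(cells))
        raise FormatError(f"{path.name}: expected 100 cells, missing {missing}")
    return AnnotationSheet(
        site_id=site_id if site_id is not None else path.stem,
        psu_index=psu_index,
        cells=cells,
        cleaning_log=log,
    )


def write_annotation_sheet(sheet: AnnotationSheet, path: str | Path) -> None:
    grid = pd.DataFrame(
        [[sheet.cells[f"{r}{c}"] for c in range(1, 11)] for r in ROW_LETTERS],
        index=list(ROW_LETTERS),
        columns=[str(c) for c in range(1, 11)],
    )
    grid.to_csv(path)


def flatten_to_records(
    sheets_and_grids: Sequence[tuple[AnnotationSheet, PSUGrid]],
    product_rasters: Mapping[str, Raster],
) -> pd.DataFrame:
    """Join sheets to product rasters on the A1-J10 cell identifiers.

    The join is total: every cell of every sheet must fall inside every
    product raster, otherwise an error names the offending cell.
    """
    rows = []
    for sheet, grid in sheets_and_grids:
        for key, (col, row) in grid.cells().items():
            rec = {
                "site_id": sheet.site_id,
                "psu": sheet.psu_index,
                "cell": key,
                "ref_code": sheet.cells[key],
            }
            for product, raster in product_rasters.items():
                if not raster.covers(col, row):
                    raise FormatError(
                        f"raster {product!r} does not cover cell {key} of "
                        f"{sheet.site_id}/{sheet.psu_index}"
                    )
                rec[product] = raster.token_at(col, row)
            rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# rasters (plain-matrix text)


def write_raster(raster: Raster, path: str | Path) -> None:
    header = {
        "classes": list(raster.classes),
        "col0": raster.col0,
        "row0": raster.row0,
        "cell_deg": raster.grid.cell_deg,
        "origin_lon": raster.grid.origin_lon,
        "origin_lat": raster.grid.origin_lat,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        np.savetxt(fh, raster.data, fmt="%d")


def read_raster(path: str | Path) -> Raster:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError("raster file missing header line")
        header = json.loads(first[1:])
        data = np.loadtxt(fh, dtype=np.int16, ndmin=2)
    grid = PixelGridSpec(
        origin_lon=header["origin_lon"],
        origin_lat=header["origin_lat"],
        cell_deg=header["cell_deg"],
    )
    return Raster(
        classes=tuple(header["classes"]),
        data=data,
        col0=header["col0"],
        row0=header["row0"],
        grid=grid,
    )


# --------------------------------------------------------------------------
# GeoJSON


def grids_to_geojson(grids: Iterable[PSUGrid]) -> dict:
    """PSU footprints as a GeoJSON FeatureCollection (lon/lat polygons)."""
    features = []
    for g in grids:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(pt) for pt in g.polygon()]],
                },
                "properties": {"site_id": g.site_id, "psu_index": g.psu_index},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj))


# --------------------------------------------------------------------------
# reports


def _config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config, sort_keys=True, default=str) if config else ""
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_report(
    results: Mapping,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
    scheme_version: str | None = None,
) -> dict:
    """Serialize results as a versioned JSON report; returns the written object."""
    report = {
        "format": "grassaudit-report/1",
        "package_version": __version__,
        "scheme_version": scheme_version,
        "seed": seed,
        "config_hash": _config_hash(config),
        "results": _jsonable(results),
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def read_report(path: str | Path) -> dict:
    report = json.loads(Path(path).read_text())
    if report.get("format") != "grassaudit-report/1":
        raise FormatError("not a grassaudit report")
    return report


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj
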