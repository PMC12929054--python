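"""Confusion matrices and map-vs-reference agreement statistics.

Pixel records (one row per annotated SSU) are scored against each land-cover
product at three scheme levels and three spatial scales:

* levels — ``binary`` (grassland / non-grassland), ``simplified`` (the shared
  harmonized vocabulary), ``full`` (typed reference classes; the map axis
  stays in simplified tokens because no product resolves grassland subtypes,
  so full-level matrices are rectangular and serve per-class counts rather
  than trace statistics);
* scales — per PSU grid, per location (pooling a site's grids), and overall.

Matrix orientation is **rows = map (predicted), columns = reference**, so
user's accuracy is a row quantity and producer's accuracy a column quantity.
Reference "U" (unfilled) pixels are excluded everywhere; reference "7"
(grassland, type unsure) counts as grassland at the binary level and is
excluded at simplified/full levels.  Undefined ratios (empty row or column)
are returned as NaN, never 0, so "no pixels" is distinguishable from
"all wrong".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scheme import (
    EXCLUDED,
    GRASSLAND,
    NON_GRASSLAND,
    UNFILLED_CODE,
    UNSURE_CODE,
    ClassificationScheme,
    SchemeError,
)

BINARY_CLASSES = (GRASSLAND, NON_GRASSLAND)

#: required columns of a pixel-record table (plus one column per product id)
RECORD_COLUMNS = ("site_id", "psu", "cell", "ref_code")


@dataclass(frozen=True)
class SSURecord:
    """One annotated 10-m pixel."""

    site_id: str
    psu: int
    cell: str
    ref_code: str
    map_codes: dict[str, str]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Count matrix with rows = map classes, columns = reference classes."""

    scheme_level: str
    row_classes: tuple[str, ...]
    col_classes: tuple[str, ...]
    counts: np.ndarray  # shape (rows, cols), non-negative ints
    n_excluded: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.row_classes), len(self.col_classes)):
            raise ValueError("counts shape does not match class labels")
        if (counts < 0).any():
            raise ValueError("negative counts")

    @property
    def classes(self) -> tuple[str, ...]:
        if self.row_classes != self.col_classes:
            raise ValueError("matrix is rectangular; no single class list")
        return self.row_classes

    @property
    def is_square(self) -> bool:
        return self.row_classes == self.col_classes

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_total(self, k: str) -> int:
        return int(self.counts[self.row_classes.index(k)].sum())

    def col_total(self, k: str) -> int:
        return int(self.counts[:, self.col_classes.index(k)].sum())

    def count(self, map_class: str, ref_class: str) -> int:
        return int(self.counts[self.row_classes.index(map_class),
                               self.col_classes.index(ref_class)])

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if (self.row_classes, self.col_classes) != (other.row_classes, other.col_classes):
            raise ValueError("cannot add matrices over different class schemes")
        return ConfusionMatrix(
            scheme_level=self.scheme_level,
            row_classes=self.row_classes,
            col_classes=self.col_classes,
            counts=self.counts + other.counts,
            n_excluded=self.n_excluded + other.n_excluded,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_classes),
                            columns=list(self.col_classes))


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy summary at one scale for one scope (PSU / location / overall)."""

    scale: str  # "PSU" | "location" | "overall"
    scope_key: str
    matrix: ConfusionMatrix
    users: dict[str, float]
    producers: dict[str, float]
    overall: float
    kappa: float


# --------------------------------------------------------------------------
# label projection


def _ref_labels(ref: pd.Series, scheme: ClassificationScheme, level: str) -> pd.Series:
    """Project reference codes to level labels; NaN means excluded."""
    if level == "binary":
        cat = {rc.code: rc.category for rc in scheme.reference_classes}
        out = ref.map(cat)
        return out.where(out != EXCLUDED)
    if level == "simplified":
        simp = {rc.code: rc.simplified for rc in scheme.reference_classes}
        return ref.map(simp)
    if level == "full":
        keep = set(scheme.full_level_codes)
        return ref.where(ref.isin(keep))
    raise ValueError(f"unknown scheme level {level!r}")


def _map_labels(tokens: pd.Series, scheme: ClassificationScheme,
                product: str, level: str) -> pd.Series:
    """Project native product tokens to level labels; NaN means excluded."""
    legend = scheme.legend(product)
    if level == "binary":
        mapping = {}
        for tok in legend.classes:
            if legend.harmonize(tok) == UNFILLED_CODE:
                mapping[tok] = None
            else:
                mapping[tok] = GRASSLAND if legend.is_grassland_token(tok) else NON_GRASSLAND
        unknown = set(tokens.dropna().unique()) - set(mapping)
        if unknown:
            raise SchemeError(f"unknown {product!r} tokens in records: {sorted(unknown)}")
        return tokens.map(mapping)
    # simplified and full both use the harmonized simplified token on the map axis
    mapping = {tok: legend.harmonize(tok) for tok in legend.classes}
    unknown = set(tokens.dropna().unique()) - set(mapping)
    if unknown:
        raise SchemeError(f"unknown {product!r} tokens in records: {sorted(unknown)}")
    out = tokens.map(mapping)
    return out.where(out != UNFILLED_CODE)


def _level_axes(scheme: ClassificationScheme, level: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    if level == "binary":
        return BINARY_CLASSES, BINARY_CLASSES
    if level == "simplified":
        return scheme.simplified_classes, scheme.simplified_classes
    if level == "full":
        return scheme.simplified_classes, scheme.full_level_codes
    raise ValueError(f"unknown scheme level {level!r}")


def build_confusion(
    records: pd.DataFrame,
    product: str,
    scheme: ClassificationScheme,
    level: str = "binary",
    scope_key: str | tuple | None = None,
) -> ConfusionMatrix:
    """Tally a confusion matrix from pixel records.

    ``scope_key`` optionally restricts to one location (``site_id``) or PSU
    (``(site_id, psu)``).  Pixels whose reference or map label is excluded at
    this level are counted in ``n_excluded``.
    """
    df = records
    if scope_key is not None:
        if isinstance(scope_key, tuple):
            df = df[(df["site_id"] == scope_key[0]) & (df["psu"] == scope_key[1])]
        else:
            df = df[df["site_id"] == scope_key]
        if df.empty:
            raise ValueError(f"unknown scope key {scope_key!r}")
    n_input = len(df)
    ref = _ref_labels(df["ref_code"], scheme, level)
    mp = _map_labels(df[product], scheme, product, level)
    keep = ref.notna() & mp.notna()
    n_excluded = int(n_input - keep.sum())
    if n_input == 0:
        raise ValueError("no records supplied")
    row_classes, col_classes = _level_axes(scheme, level)
    if keep.sum() == 0:
        counts = pd.DataFrame(0, index=list(row_classes), columns=list(col_classes))
    else:
        ri = pd.Categorical(mp[keep], categories=row_classes)
        ci = pd.Categorical(ref[keep], categories=col_classes)
        counts = pd.crosstab(ri, ci, dropna=False).reindex(
            index=list(row_classes), columns=list(col_classes), fill_value=0
        )
    return ConfusionMatrix(
        scheme_level=level,
        row_classes=row_classes,
        col_classes=col_classes,
        counts=counts.to_numpy(dtype=np.int64),
        n_excluded=n_excluded,
    )


# --------------------------------------------------------------------------
# statistics


def users_accuracy(cm: ConfusionMatrix, k: str) -> float:
    """Among pixels the map labels k, the fraction truly k (commission complement)."""
    rt = cm.row_total(k)
    if rt == 0:
        return math.nan
    return cm.count(k, k) / rt


def producers_accuracy(cm: ConfusionMatrix, k: str) -> float:
    """Among pixels truly k, the fraction the map labels k (omission complement)."""
    ct = cm.col_total(k)
    if ct == 0:
        return math.nan
    return cm.count(k, k) / ct


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total (square matrices only)."""
    if not cm.is_square:
        raise ValueError("overall accuracy requires a square matrix")
    total = cm.total
    if total == 0:
        return math.nan
    return float(np.trace(cm.counts)) / total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    if not cm.is_square:
        raise ValueError("kappa requires a square matrix")
    total = cm.total
    if total == 0:
        return math.nan
    p_o = float(np.trace(cm.counts)) / total
    rows = cm.counts.sum(axis=1) / total
    cols = cm.counts.sum(axis=0) / total
    p_e = float(rows @ cols)
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else math.nan
    return (p_o - p_e) / (1.0 - p_e)


def accuracy_from_counts(correct: int, total: int) -> float:
    """Plain proportion helper for printed-count audits (e.g. 240266/281735)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return correct / total


def class_correct_counts(
    records: pd.DataFrame, product: str, scheme: ClassificationScheme
) -> pd.DataFrame:
    """Per grassland reference class: pixels the product labelled grassland vs not.

    Returns a frame indexed by grassland reference code with columns
    ``correct`` (map says grassland) and ``incorrect``.
    """
    mp = _map_labels(records[product], scheme, product, "binary")
    out = []
    for code in scheme.grassland_codes:
        sel = (records["ref_code"] == code) & mp.notna()
        n = int(sel.sum())
        correct = int((mp[sel] == GRASSLAND).sum())
        out.append({"ref_code": code, "correct": correct, "incorrect": n - correct})
    return pd.DataFrame(out).set_index("ref_code")


def _report(cm: ConfusionMatrix, scale: str, scope_key: str) -> AccuracyReport:
    users = {k: users_accuracy(cm, k) for k in cm.row_classes}
    producers = {k: producers_accuracy(cm, k) for k in cm.col_classes if k in cm.row_classes}
    return AccuracyReport(
        scale=scale,
        scope_key=scope_key,
        matrix=cm,
        users=users,
        producers=producers,
        overall=overall_accuracy(cm),
        kappa=cohens_kappa(cm),
    )


def accuracy_by_scale(
    records: pd.DataFrame,
    product: str,
    scheme: ClassificationScheme,
    level: str = "binary",
) -> dict[str, list[AccuracyReport]]:
    """Accuracy reports at PSU, location and overall scales.

    Pooled counts at each scale equal the elementwise sum of child-scale
    counts by construction (one shared projection, grouped tallies).
    """
    if level == "full":
        raise ValueError("trace statistics are undefined at the full level")
    ref = _ref_labels(records["ref_code"], scheme, level)
    mp = _map_labels(records[product], scheme, product, level)
    keep = ref.notna() & mp.notna()
    row_classes, col_classes = _level_axes(scheme, level)

    df = pd.DataFrame(
        {
            "site_id": records["site_id"],
            "psu": records["psu"],
            "map": pd.Categorical(mp, categories=row_classes),
            "ref": pd.Categorical(ref, categories=col_classes),
            "keep": keep,
        }
    )

    n_rows, n_cols = len(row_classes), len(col_classes)

    def matrices(group_cols: list[str]) -> dict:
        # one grouped tally; categoricals guarantee a full (map, ref) block in
        # category order per group, so each slice reshapes to the matrix
        sizes = (
            df[df["keep"]]
            .groupby(group_cols + ["map", "ref"], observed=False)
            .size()
        )
        excluded = df.groupby(group_cols, sort=True)["keep"].agg(
            lambda s: int((~s).sum())
        )
        out = {}
        for key in excluded.index:
            try:
                counts = sizes.loc[key].to_numpy(dtype=np.int64).reshape(n_rows, n_cols)
            except KeyError:
                counts = np.zeros((n_rows, n_cols), dtype=np.int64)
            out[key] = ConfusionMatrix(level, row_classes, col_classes, counts,
                                       int(excluded.loc[key]))
        return out

    reports: dict[str, list[AccuracyReport]] = {"PSU": [], "location": [], "overall": []}
    psu_ms = matrices(["site_id", "psu"])
    for (site, psu), cm in psu_ms.items():
        reports["PSU"].append(_report(cm, "PSU", f"{site}/{psu}"))
    loc_ms = matrices(["site_id"])
    for site, cm in loc_ms.items():
        reports["location"].append(_report(cm, "location", str(site)))
    overall_cm = build_confusion(records, product, scheme, level)
    reports["overall"].append(_report(overall_cm, "overall", "overall"))
    return reports


def pool_matrices(matrices: Iterable[ConfusionMatrix]) -> ConfusionMatrix:
    """Elementwise sum of compatible matrices (count conservation across scales)."""
    it = iter(matrices)
    out = next(it)
    for m in it:
        out = out + m
    return out


def binary_from_simplified(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Pool a simplified-level matrix into the binary grassland dichotomy.

    Note the result counts only pixels that survive simplified-level
    exclusions (reference "7" is excluded there but included when building the
    binary matrix directly).
    """
    if cm.scheme_level != "simplified":
        raise ValueError("expects a simplified-level matrix")

    def pool(labels: tuple[str, ...], axis_counts: np.ndarray) -> np.ndarray:
        idx = [0 if lab == GRASSLAND else 1 for lab in labels]
        out = np.zeros((2, axis_counts.shape[1]), dtype=np.int64)
        for i, j in enumerate(idx):
            out[j] += axis_counts[i]
        return out

    rows = pool(cm.row_classes, cm.counts)
    cols = pool(cm.col_classes, rows.T).T
    return ConfusionMatrix(
        scheme_level="binary",
        row_classes=BINARY_CLASSES,
        col_classes=BINARY_CLASSES,
        counts=cols,
        n_excluded=cm.n_excluded,
    )
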