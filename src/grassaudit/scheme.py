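"""Reference classification scheme and product-legend harmonization.

The audit compares expert "reference" labels against land-cover product labels.
The reference vocabulary has 16 cover classes — 7 grassland (6 typed plus the
"7" code, meaning *known grassland, type unsure*) and 9 non-grassland — plus
the special code "U" for unfilled cells, which is excluded from every
denominator.  Each product (WorldCover, ESRI Land Cover, Dynamic World, or a
custom legend) carries a harmonization map projecting its native tokens into
one shared simplified scheme, and a subset of tokens counted as grassland for
binary statistics.

Three scheme levels are used throughout the package:

``binary``
    grassland vs non-grassland (reference "7" counts as grassland).
``simplified``
    the shared cohesive vocabulary products are harmonized into
    (reference "7" is excluded: its simplified type is unknown).
``full``
    the 16 typed reference classes ("7" excluded for exact-match statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

GRASSLAND = "grassland"
NON_GRASSLAND = "non-grassland"
EXCLUDED = "excluded"

UNFILLED_CODE = "U"
UNSURE_CODE = "7"

SCHEME_LEVELS = ("binary", "simplified", "full")

#: number of reference codes expected in each ternary category
_EXPECTED_PARTITION = {GRASSLAND: 7, NON_GRASSLAND: 9, EXCLUDED: 1}


class SchemeError(ValueError):
    """Raised when a scheme or legend configuration violates its invariants."""


@dataclass(frozen=True)
class ReferenceClass:
    """One reference (expert) cover class."""

    code: str
    label: str
    category: str  # grassland | non-grassland | excluded
    simplified: str | None  # token in the simplified scheme, None if unknown
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in (GRASSLAND, NON_GRASSLAND, EXCLUDED):
            raise SchemeError(f"unknown category {self.category!r} for {self.code!r}")


@dataclass(frozen=True)
class ProductLegend:
    """A land-cover product's native class vocabulary and its harmonization.

    ``harmonization`` must be total over ``classes``; tokens may map to "U"
    (e.g. cloud flags) which excludes them like an unfilled reference cell.
    ``grassland_tokens`` are the native tokens counted as grassland in binary
    statistics; ``ambiguous_tokens`` flags tokens whose grassland status is a
    definitional judgement call (e.g. ESRI's merged "rangeland").
    """

    product_id: str
    version: str
    classes: tuple[str, ...]
    harmonization: Mapping[str, str]
    grassland_tokens: frozenset[str]
    ambiguous_tokens: frozenset[str] = frozenset()

    def harmonize(self, token: str) -> str:
        """Project a native product token into the simplified scheme.

        Idempotent: simplified tokens pass through unchanged even when they
        are not native product classes.
        """
        try:
            return self.harmonization[token]
        except KeyError:
            # already-simplified tokens are fixed points
            if token in set(self.harmonization.values()) or token == UNFILLED_CODE:
                return token
            raise SchemeError(
                f"unknown token {token!r} for product {self.product_id!r}"
            ) from None

    def is_grassland_token(self, token: str) -> bool:
        return token in self.grassland_tokens


@dataclass(frozen=True)
class ClassificationScheme:
    """The full agreed scheme: reference classes, simplified vocabulary, legends."""

    version: str
    reference_classes: tuple[ReferenceClass, ...]
    simplified_classes: tuple[str, ...]
    legends: Mapping[str, ProductLegend]
    _by_code: dict = field(repr=False, default_factory=dict)
    _alias_map: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        by_code: dict[str, ReferenceClass] = {}
        alias: dict[str, str] = {}
        for rc in self.reference_classes:
            if rc.code in by_code:
                raise SchemeError(f"duplicate reference code {rc.code!r}")
            by_code[rc.code] = rc
            alias[rc.code] = rc.code
            for a in rc.aliases:
                if a in alias:
                    raise SchemeError(f"duplicate alias {a!r}")
                alias[a] = rc.code
        counts = {cat: 0 for cat in _EXPECTED_PARTITION}
        for rc in by_code.values():
            counts[rc.category] += 1
        if counts != _EXPECTED_PARTITION:
            raise SchemeError(
                "reference partition must be 7 grassland / 9 non-grassland / "
                f"1 excluded, got {counts}"
            )
        for rc in by_code.values():
            if rc.simplified is not None and rc.simplified not in self.simplified_classes:
                raise SchemeError(
                    f"simplified token {rc.simplified!r} of {rc.code!r} not in scheme"
                )
        for legend in self.legends.values():
            missing = set(legend.classes) - set(legend.harmonization)
            if missing:
                raise SchemeError(
                    f"legend {legend.product_id!r} missing harmonization for {sorted(missing)}"
                )
            for tok, simp in legend.harmonization.items():
                if simp != UNFILLED_CODE and simp not in self.simplified_classes:
                    raise SchemeError(
                        f"legend {legend.product_id!r} harmonizes {tok!r} to unknown "
                        f"simplified token {simp!r}"
                    )
        object.__setattr__(self, "_by_code", by_code)
        object.__setattr__(self, "_alias_map", alias)

    # -- reference-side lookups -------------------------------------------------

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(rc.code for rc in self.reference_classes)

    @property
    def grassland_codes(self) -> tuple[str, ...]:
        return tuple(rc.code for rc in self.reference_classes if rc.category == GRASSLAND)

    @property
    def full_level_codes(self) -> tuple[str, ...]:
        """Typed reference codes used for full-level exact-match statistics."""
        return tuple(
            rc.code
            for rc in self.reference_classes
            if rc.category != EXCLUDED and rc.code != UNSURE_CODE
        )

    def reference_class(self, code: str) -> ReferenceClass:
        try:
            return self._by_code[code]
        except KeyError:
            raise SchemeError(f"unknown reference code {code!r}") from None

    def to_binary(self, code: str) -> str:
        """Ternary status of a reference code or simplified token."""
        if code in self._by_code:
            return self._by_code[code].category
        if code in self.simplified_classes:
            return GRASSLAND if code == GRASSLAND else NON_GRASSLAND
        raise SchemeError(f"unknown code {code!r}")

    def simplified_of_ref(self, code: str) -> str | None:
        """Simplified token of a reference code; None when excluded/unknown."""
        return self.reference_class(code).simplified

    def legend(self, product_id: str) -> ProductLegend:
        try:
            return self.legends[product_id]
        except KeyError:
            raise SchemeError(f"no legend for product {product_id!r}") from None

    # -- annotation cleaning ----------------------------------------------------

    def clean_annotation(
        self, raw: object, context_code: str | None = None
    ) -> tuple[str, str | None]:
        """Standardize one raw annotation cell value.

        Returns ``(code, log)`` where ``log`` is None for untouched values and
        a human-readable provenance string for every change made.  Blanks
        become "U".  Unrecognized tokens are corrected to ``context_code``
        when one is supplied and is a plausible typo source (the raw token
        starts with the context code, e.g. "12" in an all-"1" grid -> "1");
        otherwise they are flagged and kept as "U".
        """
        text = "" if raw is None else str(raw).strip()
        if text != str(raw):
            log = f"normalized {raw!r} -> {text!r}"
        else:
            log = None
        if text == "":
            return UNFILLED_CODE, log or "blank cell -> 'U'"
        if text in self._alias_map:
            # alias -> canonical code is deterministic recoding, not a correction
            return self._alias_map[text], log
        upper = text.upper()
        if upper in self._alias_map:
            return self._alias_map[upper], f"case-normalized {text!r} -> {self._alias_map[upper]!r}"
        if context_code is not None:
            ctx = self._alias_map.get(context_code, context_code)
            raw_ctx = context_code
            if text.startswith(raw_ctx) or (ctx in self._by_code and text.startswith(ctx)):
                return ctx, f"context-corrected {text!r} -> {ctx!r} (neighbourhood majority {raw_ctx!r})"
        return UNFILLED_CODE, f"unresolvable token {text!r} kept as 'U'"


def load_scheme(config: str | Mapping) -> ClassificationScheme:
    """Build a validated :class:`ClassificationScheme` from structured text.

    ``config`` is either a JSON string or an already-parsed mapping with keys
    ``version``, ``reference_classes``, ``simplified_classes``, ``legends``.
    Unknown keys are rejected.
    """
    if isinstance(config, str):
        config = json.loads(config)
    known = {"version", "reference_classes", "simplified_classes", "legends"}
    extra = set(config) - known
    if extra:
        raise SchemeError(f"unknown config keys: {sorted(extra)}")
    missing = known - set(config)
    if missing:
        raise SchemeError(f"missing config keys: {sorted(missing)}")

    ref_known = {"code", "label", "category", "simplified", "aliases"}
    refs = []
    for entry in config["reference_classes"]:
        extra = set(entry) - ref_known
        if extra:
            raise SchemeError(f"unknown reference-class keys: {sorted(extra)}")
        refs.append(
            ReferenceClass(
                code=str(entry["code"]),
                label=entry["label"],
                category=entry["category"],
                simplified=entry.get("simplified"),
                aliases=tuple(entry.get("aliases", ())),
            )
        )
    leg_known = {"product_id", "version", "classes", "harmonization",
                 "grassland_tokens", "ambiguous_tokens"}
    legends = {}
    for entry in config["legends"]:
        extra = set(entry) - leg_known
        if extra:
            raise SchemeError(f"unknown legend keys: {sorted(extra)}")
        legend = ProductLegend(
            product_id=entry["product_id"],
            version=entry["version"],
            classes=tuple(entry["classes"]),
            harmonization=dict(entry["harmonization"]),
            grassland_tokens=frozenset(entry["grassland_tokens"]),
            ambiguous_tokens=frozenset(entry.get("ambiguous_tokens", ())),
        )
        if legend.product_id in legends:
            raise SchemeError(f"duplicate legend {legend.product_id!r}")
        if legend.product_id in ("wc", "dw") and not legend.grassland_tokens:
            raise SchemeError(f"legend {legend.product_id!r} needs grassland tokens")
        legends[legend.product_id] = legend
    return ClassificationScheme(
        version=config["version"],
        reference_classes=tuple(refs),
        simplified_classes=tuple(config["simplified_classes"]),
        legends=legends,
    )


def default_scheme() -> ClassificationScheme:
    """The shipped default scheme (16 reference classes, WC/LC/DW legends)."""
    text = resources.files("grassaudit.data").joinpath("default_scheme.json").read_text()
    return load_scheme(text)


def harmonize(token: str, legend: ProductLegend) -> str:
    """Functional alias for :meth:`ProductLegend.harmonize`."""
    return legend.harmonize(token)
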