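"""Enzyme conversion arithmetic for yeast functional assays.

Conversion for a substrate is 100 · Σ(product areas) / (Σ(product areas) +
substrate area) over the GC-FID peak areas of the substrate and all products
expected from the single introduced enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .fattyacids import (
    EnzymeActivity,
    FattyAcid,
    close_pathway,
    parse_fatty_acid,
)

__all__ = [
    "AreaTable",
    "SubstrateConversion",
    "UndefinedConversionError",
    "expected_products",
    "conversion_percent",
    "summarize_assay",
]

MAX_CARBONS = 24


class UndefinedConversionError(ValueError):
    """Raised when both the substrate and all products have zero area."""


@dataclass
class AreaTable:
    """Peak areas keyed by fatty-acid shorthand; units arbitrary but uniform."""

    areas: dict[FattyAcid, float]

    @classmethod
    def from_rows(cls, rows: Sequence[tuple[str, float]]) -> "AreaTable":
        areas: dict[FattyAcid, float] = {}
        for shorthand, area in rows:
            fa = parse_fatty_acid(shorthand)
            if fa in areas:
                raise ValueError(f"duplicate fatty-acid key {fa}")
            if area < 0:
                raise ValueError(f"negative area for {fa}")
            areas[fa] = float(area)
        return cls(areas)

    def get(self, fa: FattyAcid, default: float | None = None) -> float | None:
        return self.areas.get(fa, default)

    def __contains__(self, fa: FattyAcid) -> bool:
        return fa in self.areas


def expected_products(
    substrate: FattyAcid,
    activities: Sequence[EnzymeActivity],
    max_carbons: int = MAX_CARBONS,
) -> list[FattyAcid]:
    """Closure of one substrate under a single enzyme's activities, substrate excluded.

    The introduced enzyme acts iteratively in yeast, so multi-step products
    (e.g. C18 → C20 → C22 for an elongase admitting C18 and C20) are included.
    Ordered by breadth-first discovery.
    """
    closure = close_pathway(activities, [substrate], max_carbons=max_carbons)
    products = [fa for fa in closure.acids if fa != substrate]
    products.sort(key=lambda fa: (fa.carbons, fa.double_bonds, fa.omega or 0))
    return products


def conversion_percent(
    substrate_area: float, product_areas: Sequence[float]
) -> float:
    """100 · Σ(products) / (Σ(products) + substrate); in [0, 100]."""
    if substrate_area < 0 or any(a < 0 for a in product_areas):
        raise ValueError("areas must be non-negative")
    total_products = sum(product_areas)
    denom = total_products + substrate_area
    if denom == 0:
        raise UndefinedConversionError(
            "conversion undefined: substrate and all product areas are zero"
        )
    return 100.0 * total_products / denom


@dataclass
class SubstrateConversion:
    substrate: FattyAcid
    products: list[FattyAcid]
    conversion: float | None
    error: str | None = None


def summarize_assay(
    table: AreaTable,
    activities: Sequence[EnzymeActivity],
    substrates: Sequence[FattyAcid | str],
) -> list[SubstrateConversion]:
    """One conversion per assayed substrate; missing product rows count as area 0.

    A substrate absent from the table yields a per-substrate error entry rather
    than a global failure.
    """
    out = []
    for sub in substrates:
        fa = parse_fatty_acid(sub) if isinstance(sub, str) else sub
        products = expected_products(fa, activities)
        if fa not in table:
            out.append(
                SubstrateConversion(
                    fa, products, None, error=f"substrate {fa} absent from area table"
                )
            )
            continue
        substrate_area = table.get(fa)
        product_areas = [table.get(p, 0.0) for p in products]
        try:
            pct = conversion_percent(substrate_area, product_areas)
        except UndefinedConversionError as exc:
            out.append(SubstrateConversion(fa, products, None, error=str(exc)))
            continue
        out.append(SubstrateConversion(fa, products, pct))
    return out
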