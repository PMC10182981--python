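"""easTILs% scoring: region restriction, area accounting, dichotomization.

``easTILs% = 100 * lymphocyte area (mm²) / stromal area (mm²)`` where the
stromal area is the summed invasive-tumor region area minus the summed
tumor-cell area.  Lymphocytes anywhere inside the region — including
intratumoral ones — count toward the numerator.  Scores are dichotomized at
19.9% (easTILs%) or 20% (pathologist sTILs%), "high" meaning strictly above
the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .segmentation import CellObject

__all__ = [
    "RegionAnnotation",
    "AreaSummary",
    "TILCategory",
    "EASTILS_CUTOFF",
    "STILS_CUTOFF",
    "assign_cells_to_region",
    "summarize_areas",
    "compute_eastils",
    "dichotomize",
]

EASTILS_CUTOFF = 19.9
STILS_CUTOFF = 20.0

UM2_PER_MM2 = 1e6


def um2_to_mm2(area_um2: float) -> float:
    return area_um2 / UM2_PER_MM2


@dataclass
class RegionAnnotation:
    """Invasive-tumor region: included polygons minus excluded sub-polygons.

    Exclusions model non-invasive lesions and normal breast structures whose
    inflammatory infiltrates must not contribute to the score.
    All coordinates in µm.
    """

    polygons: list[BaseGeometry]
    exclusions: list[BaseGeometry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in list(self.polygons) + list(self.exclusions):
            if not p.is_valid:
                raise ValueError("region polygons must be simple (non-self-intersecting)")
        self._geometry = unary_union(self.polygons)
        if self.exclusions:
            self._geometry = self._geometry.difference(unary_union(self.exclusions))
        if self._geometry.area <= 0:
            raise ValueError("region has non-positive area")

    @property
    def geometry(self) -> BaseGeometry:
        return self._geometry

    @property
    def area_um2(self) -> float:
        return self._geometry.area


@dataclass
class AreaSummary:
    """Per-class area accounting inside the invasive-tumor region (mm²)."""

    region_area_mm2: float
    class_areas_mm2: dict[str, float]
    stromal_area_mm2: float
    eastils_percent: float | None

    @property
    def lymphocyte_area_mm2(self) -> float:
        return self.class_areas_mm2["lymphocyte"]

    @property
    def tumor_area_mm2(self) -> float:
        return self.class_areas_mm2["tumor"]


@dataclass
class TILCategory:
    label: str  # "high" | "low"
    cutoff: float
    score: float


class UndefinedScoreError(ValueError):
    """easTILs% is undefined when the stromal area is non-positive."""


def assign_cells_to_region(cells: list[CellObject], region: RegionAnnotation) -> list[CellObject]:
    """Keep cells whose nucleus centroid lies within the region (closed boundary).

    Cells centred inside an exclusion hole are dropped.  Area accounting
    later clips cell polygons to the region, so boundary cells are not
    double-counted.
    """
    geom = region.geometry
    shapely.prepare(geom)
    return [c for c in cells if geom.covers(Point(c.centroid_um))]


def summarize_areas(
    cells_in_region: list[CellObject],
    region: RegionAnnotation,
    area_basis: str = "cell",
) -> AreaSummary:
    """Sum clipped per-class areas within the region and derive easTILs%.

    ``area_basis`` selects whether the expanded cell polygon (default) or the
    nucleus polygon represents a cell's occupied area.  All cells must be
    classified first.
    """
    if area_basis not in ("cell", "nucleus"):
        raise ValueError("area_basis must be 'cell' or 'nucleus'")
    from .synthetic import CLASSES

    geom = region.geometry
    shapely.prepare(geom)
    class_um2 = {c: 0.0 for c in CLASSES}
    for cell in cells_in_region:
        if cell.class_label == "unclassified" or cell.class_label not in class_um2:
            raise ValueError("unclassified cells present; classification must precede scoring")
        poly = cell.cell_polygon if area_basis == "cell" else cell.nucleus_polygon
        if poly is None:
            raise ValueError(f"cell lacks a {area_basis} polygon")
        class_um2[cell.class_label] += poly.intersection(geom).area

    region_mm2 = um2_to_mm2(region.area_um2)
    class_mm2 = {k: um2_to_mm2(v) for k, v in class_um2.items()}
    stromal_mm2 = region_mm2 - class_mm2["tumor"]
    eastils = (
        100.0 * class_mm2["lymphocyte"] / stromal_mm2 if stromal_mm2 > 0 else None
    )
    return AreaSummary(region_mm2, class_mm2, stromal_mm2, eastils)


def compute_eastils(summary: AreaSummary) -> float:
    """easTILs% = 100 × lymphocyte area / stromal area (both mm²)."""
    if summary.stromal_area_mm2 <= 0:
        raise UndefinedScoreError("stromal area is non-positive; easTILs% undefined")
    return 100.0 * summary.lymphocyte_area_mm2 / summary.stromal_area_mm2


def dichotomize(score: float, cutoff: float = EASTILS_CUTOFF) -> TILCategory:
    """High iff score strictly exceeds the cutoff; the cutoff itself is low."""
    if score < 0:
        raise ValueError("score must be nonnegative")
    return TILCategory("high" if score > cutoff else "low", cutoff, score)
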