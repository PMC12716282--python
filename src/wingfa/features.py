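"""Per-cell and whole-wing geometric descriptors.

Cell length and width are principal-axis extents of the vertex cloud (not
image-axis bounding boxes), which makes them rotation invariant.
Circularity is the isoperimetric quotient ``4*pi*A / P**2``: 1 for a circle
and smaller for elongated cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    CellPolygon,
    WingGeometry,
    polygon_area,
    polygon_centroid,
    polygon_perimeter,
    principal_extents,
)

__all__ = ["CellFeatures", "WingFeatures", "cell_features", "wing_features", "wing_load",
           "cell_feature_table", "wing_feature_row"]


@dataclass
class CellFeatures:
    id: int
    area: float  # um^2
    perimeter: float  # um
    length: float  # um, major principal extent
    width: float  # um, minor principal extent
    circularity: float  # 4*pi*A/P^2, dimensionless
    centroid: np.ndarray  # um
    set_label: int | None = None


@dataclass
class WingFeatures:
    area: float  # um^2
    perimeter: float  # um
    length: float  # um
    width: float  # um
    n_cells: int
    n_junctions: int


def cell_features(cell: CellPolygon) -> CellFeatures:
    area = polygon_area(cell.vertices)
    if area <= 0:
        raise ValueError(f"cell {cell.id}: degenerate (zero-area) polygon")
    perim = polygon_perimeter(cell.vertices)
    length, width, _ = principal_extents(cell.vertices)
    return CellFeatures(
        id=cell.id,
        area=area,
        perimeter=perim,
        length=length,
        width=width,
        circularity=4.0 * np.pi * area / perim**2,
        centroid=polygon_centroid(cell.vertices),
        set_label=cell.set_label,
    )


def wing_features(wing: WingGeometry) -> WingFeatures:
    length, width, _ = principal_extents(wing.outline)
    return WingFeatures(
        area=polygon_area(wing.outline),
        perimeter=polygon_perimeter(wing.outline),
        length=length,
        width=width,
        n_cells=wing.n_cells,
        n_junctions=wing.n_junctions,
    )


def wing_load(wet_weight_mg: float, mean_wing_area_mm2: float) -> float:
    """Wing load in mg/mm^2: body wet weight over mean wing area of a pair."""
    if wet_weight_mg <= 0 or mean_wing_area_mm2 <= 0:
        raise ValueError("wet weight and wing area must be positive")
    return wet_weight_mg / mean_wing_area_mm2


def cell_feature_table(wing: WingGeometry) -> pd.DataFrame:
    """Tidy per-cell feature table, one row per cell, indexed by cell id."""
    rows = []
    for c in wing.cells:
        f = cell_features(c)
        rows.append(
            {"id": f.id, "area": f.area, "perimeter": f.perimeter, "length": f.length,
             "width": f.width, "circularity": f.circularity,
             "centroid_x": f.centroid[0], "centroid_y": f.centroid[1],
             "set_label": f.set_label}
        )
    df = pd.DataFrame(rows, columns=["id", "area", "perimeter", "length", "width",
                                     "circularity", "centroid_x", "centroid_y", "set_label"])
    return df.set_index("id")


def wing_feature_row(wing: WingGeometry) -> dict:
    f = wing_features(wing)
    return {"side": wing.side, "wing_type": wing.wing_type, "area": f.area,
            "perimeter": f.perimeter, "length": f.length, "width": f.width,
            "n_cells": f.n_cells, "n_junctions": f.n_junctions}
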