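"""Geometric containers and planar-polygon primitives.

All coordinates are physical (micrometres) with anatomical "up" as +y.
A :class:`WingGeometry` holds the three layers extracted from one wing:
the outer outline, the membrane cells (polygons tiling the outline
interior) and the vein junctions (points where three or more veins meet).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CellPolygon",
    "WingGeometry",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "principal_extents",
    "resample_closed",
]


def _as_vertices(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError(f"vertex array must have shape (n, 2), got {a.shape}")
    return a


def polygon_area(vertices) -> float:
    """Unsigned polygon area (shoelace formula)."""
    v = _as_vertices(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(vertices) -> float:
    v = _as_vertices(vertices)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(vertices) -> np.ndarray:
    """Area centroid (centre of gravity) of a simple polygon."""
    v = _as_vertices(vertices)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-300:
        return v.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def principal_extents(vertices) -> tuple[float, float, np.ndarray]:
    """Extents of the vertex cloud along its principal axes.

    Returns ``(length, width, axes)`` with ``length >= width``; ``axes``
    rows are the unit principal directions (major first).  For isotropic
    vertex clouds (e.g. squares) the axes degenerate to the coordinate
    axes, which keeps the result deterministic.
    """
    v = _as_vertices(vertices)
    c = v.mean(axis=0)
    d = v - c
    cov = d.T @ d / max(len(v), 1)
    w, vec = np.linalg.eigh(cov)
    # eigh returns ascending order; major axis last
    axes = vec.T[::-1]
    proj = d @ axes.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    length, width = float(max(ext)), float(min(ext))
    return length, width, axes


def resample_closed(vertices, n: int = 500) -> np.ndarray:
    """Resample a closed polyline to *n* arc-length-uniform points."""
    v = _as_vertices(vertices)
    closed = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate outline: zero perimeter")
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


@dataclass
class CellPolygon:
    """One wing-membrane cell: a simple polygon in micrometres."""

    id: int
    vertices: np.ndarray
    set_label: int | None = None  # 1 = proximal section, 2 = distal section

    def __post_init__(self):
        self.vertices = _as_vertices(self.vertices)

    @property
    def area(self) -> float:
        return polygon_area(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.vertices)


@dataclass
class WingGeometry:
    """One wing's outline, cells, and vein junctions in physical units."""

    side: str  # "left" | "right"
    wing_type: str  # "front" | "hind"
    outline: np.ndarray
    cells: list[CellPolygon] = field(default_factory=list)
    junction_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    junction_xy: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    junction_degree: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    scale_um_per_px: float = 1.0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.wing_type not in ("front", "hind"):
            raise ValueError(f"wing_type must be 'front' or 'hind', got {self.wing_type!r}")
        self.outline = _as_vertices(self.outline)
        self.junction_xy = np.asarray(self.junction_xy, dtype=float).reshape(-1, 2)
        self.junction_ids = np.asarray(self.junction_ids, dtype=int)
        self.junction_degree = np.asarray(self.junction_degree, dtype=int)

    # -- basic measurements -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_junctions(self) -> int:
        return len(self.junction_ids)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.outline)

    @property
    def length(self) -> float:
        return principal_extents(self.outline)[0]

    # -- rigid transforms (return new geometries) ---------------------------
    def _apply(self, fn) -> "WingGeometry":
        cells = [CellPolygon(c.id, fn(c.vertices), c.set_label) for c in self.cells]
        return replace(
            self,
            outline=fn(self.outline),
            cells=cells,
            junction_xy=fn(self.junction_xy) if len(self.junction_xy) else self.junction_xy,
        )

    def translated(self, dxy) -> "WingGeometry":
        dxy = np.asarray(dxy, dtype=float)
        return self._apply(lambda p: p + dxy)

    def rotated(self, angle_rad: float, about=(0.0, 0.0)) -> "WingGeometry":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        about = np.asarray(about, dtype=float)
        return self._apply(lambda p: (p - about) @ rot.T + about)

    def reflected_x(self) -> "WingGeometry":
        """Mirror across the vertical axis (x -> -x)."""
        return self._apply(lambda p: p * np.array([-1.0, 1.0]))

    # -- validation ---------------------------------------------------------
    def validate(self, strict: bool = False) -> None:
        """Check structural invariants; `strict` adds shapely simplicity tests."""
        if not np.all(np.isfinite(self.outline)):
            raise ValueError("outline contains non-finite coordinates")
        if len(self.outline) < 3:
            raise ValueError("outline must have at least 3 vertices")
        for c in self.cells:
            if polygon_area(c.vertices) <= 0:
                raise ValueError(f"cell {c.id} has non-positive area")
        if len(self.junction_degree) and self.junction_degree.min() < 3:
            raise ValueError("junction with degree < 3")
        if strict:
            from shapely.geometry import Polygon

            if not Polygon(self.outline).is_simple:
                raise ValueError("outline is not a simple polygon")
            for c in self.cells:
                if not Polygon(c.vertices).is_valid:
                    raise ValueError(f"cell {c.id} polygon is invalid")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "wing_type": self.wing_type,
            "scale_um_per_px": self.scale_um_per_px,
            "outline": self.outline.tolist(),
            "cells": [
                {"id": int(c.id), "set_label": c.set_label, "vertices": c.vertices.tolist()}
                for c in self.cells
            ],
            "junctions": [
                {"id": int(i), "x": float(x), "y": float(y), "degree": int(d)}
                for i, (x, y), d in zip(self.junction_ids, self.junction_xy, self.junction_degree)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WingGeometry":
        junctions = d.get("junctions", [])
        return cls(
            side=d["side"],
            wing_type=d["wing_type"],
            outline=np.asarray(d["outline"], dtype=float),
            cells=[
                CellPolygon(c["id"], np.asarray(c["vertices"], dtype=float), c.get("set_label"))
                for c in d.get("cells", [])
            ],
            junction_ids=np.array([j["id"] for j in junctions], dtype=int),
            junction_xy=np.array([[j["x"], j["y"]] for j in junctions], dtype=float).reshape(-1, 2),
            junction_degree=np.array([j["degree"] for j in junctions], dtype=int),
            scale_um_per_px=float(d.get("scale_um_per_px", 1.0)),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path) -> "WingGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))
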