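"""Synthetic wing-pair and cohort generator.

Emulates the structure of a paired-wing fluctuating-asymmetry (FA) study on
damselflies: each individual carries a left and a right wing, mirror images
of one shared "true" wing, with independent per-side noise on the vein
junctions (the FA channel), optional directional offsets applied to the
right side only (directional asymmetry), an antisymmetry switch (random-sign
offset), and rare cell merge/split events that perturb the cell count.

The tessellation is a smoothly deformed rectangular lattice clipped to an
elliptical-teardrop outline.  It is not a biological venation model; the
downstream asymmetry metrics are geometry-agnostic, so a lattice carries
them just as well while providing an exact ground truth (cell and junction
correspondences between the sides).

Cohorts add stressor structure: a continuous dose column or a 2x2 factorial
(larvicide treatment x hydrological regime), sex, a wet-weight observation
model, and an ``effect_map`` that scales generator parameters per factor.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CellPolygon, WingGeometry, polygon_perimeter

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "generate_wing_pair",
    "generate_landmark_pair",
    "render_wing_image",
    "generate_cohort",
    "mesocosm_design",
    "insecticide_design",
    "LANDMARK_ANCHORS",
]

# 12 landmark anchors as (t, u): t = relative position along the wing axis,
# u = relative position across the local half-width (+1 leading edge, -1
# trailing edge).  Layout loosely follows odonate conventions: basal cross
# veins (1-3), nodus on the leading edge (4), interior radius points (5-6),
# cubital vein (7), media branches (8-10), pterostigma margin (11-12).
LANDMARK_ANCHORS = np.array(
    [
        [0.06, 0.75],
        [0.06, -0.75],
        [0.18, -0.90],
        [0.45, 0.95],
        [0.35, 0.35],
        [0.55, 0.30],
        [0.22, 0.10],
        [0.52, 0.60],
        [0.66, 0.45],
        [0.78, 0.25],
        [0.82, 0.90],
        [0.92, 0.80],
    ]
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Defaults are chosen to resemble a damselfly front wing (~20 mm long,
    ~250 membrane cells) and produce asymmetry magnitudes on the order of
    those reported for real material (mean junction displacements of the
    order of 100 um, FA scores of the order of 0.01 shape units).
    """

    n_individuals: int = 60
    cells_target: int = 250
    outline_length_mm: float = 20.0
    outline_aspect: float = 4.5  # length / width
    fa_position_sd_um: float = 50.0  # per-side junction jitter
    fa_shape_sd: float = 0.03  # extra jitter as a fraction of the lattice pitch
    directional_offset_um: tuple[float, float] = (0.0, 0.0)  # right wings only
    antisymmetry_offset_um: float = 0.0  # random-sign x offset on right wings
    count_perturb_prob: float = 0.5  # P(one merge/split event per wing)
    count_perturb_mode: str = "both"  # "merge" | "split" | "both"
    count_perturb_sides: tuple[str, ...] = ("left", "right")  # sides eligible for events
    fa_region: str = "none"  # "none" | "proximal" | "distal"
    fa_region_factor: float = 3.0  # jitter multiplier inside fa_region
    split_fraction: float = 0.55  # proximal/distal (Set 1/Set 2) boundary
    size_cv: float = 0.04  # between-individual lognormal sd of wing length
    effect_map: dict = field(default_factory=dict)  # factor -> {param: multiplier}
    sex_effect: float = 0.95  # male size multiplier
    wet_weight_mg: float = 24.0  # female median wet weight
    wet_weight_cv: float = 0.12
    male_weight_factor: float = 0.88
    wet_weight_gain_mg: float = 8.0
    days_to_emergence_mean: float = 28.2
    wing_types: tuple[str, ...] = ("front",)
    seed: int = 0

    def validate(self) -> None:
        if self.cells_target < 4:
            raise ValueError("cells_target must be >= 4")
        for name in ("fa_position_sd_um", "fa_shape_sd", "size_cv", "wet_weight_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.count_perturb_prob <= 1.0:
            raise ValueError("count_perturb_prob must be in [0, 1]")
        if self.count_perturb_mode not in ("merge", "split", "both"):
            raise ValueError("count_perturb_mode must be merge|split|both")
        if self.fa_region not in ("none", "proximal", "distal"):
            raise ValueError("fa_region must be none|proximal|distal")
        if self.outline_length_mm <= 0 or self.outline_aspect <= 0:
            raise ValueError("outline dimensions must be positive")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        from pathlib import Path

        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        for key in ("directional_offset_um", "wing_types"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact per-individual truth the generator knows and analyses estimate."""

    individual: int
    wing_type: str
    length_um: float
    width_um: float
    cell_pairs: list[tuple[int, int]]
    junction_pairs: list[tuple[int, int]]
    unmatched_cells_left: list[int]
    unmatched_cells_right: list[int]
    fa_region: str
    fa_position_sd_um: float
    directional_offset_um: tuple[float, float]


# ---------------------------------------------------------------------------
# outline and lattice
# ---------------------------------------------------------------------------

def _half_width_profile(t: np.ndarray) -> np.ndarray:
    """Relative half-width of the teardrop outline at relative position t."""
    t = np.asarray(t, dtype=float)
    e = np.sqrt(np.clip(1.0 - (2.0 * t - 1.0) ** 2, 0.0, None))
    return e * (1.0 - 0.18 * (2.0 * t - 1.0))


def _rng_for(config: SyntheticConfig, individual_index: int, stream: int = 0) -> np.random.Generator:
    """Counter-based per-individual stream from one master seed."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(individual_index, stream))
    return np.random.default_rng(ss)


class _Lattice:
    """Deformed rectangular lattice clipped to the teardrop outline.

    Cells are stored as tuples of node indices into a flat node array so that
    per-side noise moves the nodes and every cell polygon follows exactly.
    """

    def __init__(self, L: float, W: float, cells_target: int, rng: np.random.Generator):
        fill = 0.72  # teardrop area relative to its bounding box
        h = np.sqrt(fill * L * W / cells_target)
        self.ncol = max(4, int(round(L / h)))
        self.nrow = max(2, int(round(W / h)))
        xs = np.linspace(0.0, L, self.ncol + 1)
        ys = np.linspace(-W / 2.0, W / 2.0, self.nrow + 1)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")  # index [i, j]
        nodes = np.column_stack([gx.ravel(), gy.ravel()])  # id = i*(nrow+1)+j
        self._nid = lambda i, j: i * (self.nrow + 1) + j

        inside = np.abs(gy) < (W / 2.0) * _half_width_profile(gx / L) - 1e-9
        keep = np.zeros((self.ncol, self.nrow), dtype=bool)
        for i in range(self.ncol):
            for j in range(self.nrow):
                keep[i, j] = inside[i, j] and inside[i + 1, j] and inside[i + 1, j + 1] and inside[i, j + 1]
        # largest 4-connected component only (guards against stray cells)
        from scipy import ndimage

        lab, n = ndimage.label(keep)
        if n == 0:
            raise ValueError("no lattice cell fits inside the outline")
        if n > 1:
            sizes = ndimage.sum(keep, lab, index=range(1, n + 1))
            keep = lab == (1 + int(np.argmax(sizes)))
        self.keep = keep

        # smooth deformation field shared by both sides (the "true" wing)
        amp = 0.18 * min(L / self.ncol, W / self.nrow)
        k1, k2 = rng.integers(1, 3, size=2)
        p = rng.uniform(0, 2 * np.pi, size=4)
        X, Y = nodes[:, 0], nodes[:, 1]
        dx = amp * np.sin(2 * np.pi * k1 * X / L + p[0]) * np.cos(np.pi * k2 * Y / W + p[1])
        dy = amp * np.cos(2 * np.pi * k2 * X / L + p[2]) * np.sin(np.pi * k1 * Y / W + p[3])
        self.nodes_true = nodes + np.column_stack([dx, dy])
        self.base_t = nodes[:, 0] / L  # relative axial position of each node
        self.L, self.W = L, W
        self.pitch = min(L / self.ncol, W / self.nrow)

        self.cells: list[tuple[int, tuple[int, ...]]] = []
        self.cell_col: dict[int, int] = {}
        for i in range(self.ncol):
            for j in range(self.nrow):
                if keep[i, j]:
                    cid = i * self.nrow + j
                    quad = (self._nid(i, j), self._nid(i + 1, j), self._nid(i + 1, j + 1), self._nid(i, j + 1))
                    self.cells.append((cid, quad))
                    self.cell_col[cid] = i
        self.xs = xs

    def neighbors(self) -> list[tuple[int, int, str]]:
        """(i, j, direction) of kept cells with a kept right/top neighbor."""
        out = []
        for i in range(self.ncol):
            for j in range(self.nrow):
                if not self.keep[i, j]:
                    continue
                if i + 1 < self.ncol and self.keep[i + 1, j]:
                    out.append((i, j, "right"))
                if j + 1 < self.nrow and self.keep[i, j + 1]:
                    out.append((i, j, "top"))
        return out


def _edges_of(cells: list[tuple[int, tuple[int, ...]]]) -> dict[tuple[int, int], int]:
    """Undirected edge -> incidence count over all cell boundaries."""
    edges: dict[tuple[int, int], int] = {}
    for _, ring in cells:
        n = len(ring)
        for k in range(n):
            a, b = ring[k], ring[(k + 1) % n]
            e = (a, b) if a < b else (b, a)
            edges[e] = edges.get(e, 0) + 1
    return edges


def _chain_boundary(edges: dict[tuple[int, int], int]) -> list[int]:
    """Order the incidence-1 edges into a single closed node loop."""
    boundary = [e for e, c in edges.items() if c == 1]
    if not boundary:
        raise ValueError("no boundary edges")
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    if any(len(v) != 2 for v in adj.values()):
        raise ValueError("degenerate tessellation: boundary is not a single loop")
    start = min(adj)
    loop = [start]
    prev, cur = None, start
    while True:
        nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
        if nxt == start:
            break
        loop.append(nxt)
        prev, cur = cur, nxt
        if len(loop) > len(boundary) + 1:
            raise ValueError("degenerate tessellation: boundary walk did not close")
    if len(loop) != len(boundary):
        raise ValueError("degenerate tessellation: multiple boundary loops")
    return loop


def _junctions_from_cells(cells) -> tuple[np.ndarray, np.ndarray]:
    """Node ids with vein degree >= 3 and their degrees."""
    edges = _edges_of(cells)
    deg: dict[int, int] = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    ids = np.array(sorted(i for i, d in deg.items() if d >= 3), dtype=int)
    degrees = np.array([deg[i] for i in ids], dtype=int)
    return ids, degrees


def _perturb_count(
    cells: list[tuple[int, tuple[int, ...]]],
    lat: _Lattice,
    nodes: np.ndarray,
    rng: np.random.Generator,
    mode: str,
    force: str | None = None,
) -> tuple[list, np.ndarray, list[int], int | None]:
    """Apply one merge or split event; returns (cells, nodes, removed_ids, new_id)."""
    op = force
    if op is None:
        op = mode if mode != "both" else ("merge" if rng.random() < 0.5 else "split")
    cells = list(cells)
    nid = lat._nid
    if op == "merge":
        pairs = lat.neighbors()
        present = {cid for cid, _ in cells}
        pairs = [
            (i, j, d)
            for (i, j, d) in pairs
            if (i * lat.nrow + j) in present
            and ((i + 1) * lat.nrow + j if d == "right" else i * lat.nrow + j + 1) in present
        ]
        if not pairs:
            return cells, nodes, [], None
        i, j, d = pairs[rng.integers(len(pairs))]
        ca = i * lat.nrow + j
        if d == "right":
            cb = (i + 1) * lat.nrow + j
            ring = (nid(i, j), nid(i + 1, j), nid(i + 2, j), nid(i + 2, j + 1), nid(i + 1, j + 1), nid(i, j + 1))
        else:
            cb = i * lat.nrow + j + 1
            ring = (nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i + 1, j + 2), nid(i, j + 2), nid(i, j + 1))
        new_id = lat.ncol * lat.nrow + 1 + max(ca, cb)
        cells = [c for c in cells if c[0] not in (ca, cb)] + [(new_id, ring)]
        return cells, nodes, [ca, cb], new_id
    # split: halve one quad vertically through mid-edge nodes
    quads = [(cid, r) for cid, r in cells if len(r) == 4]
    if not quads:
        return cells, nodes, [], None
    cid, (a, b, c, d_) = quads[rng.integers(len(quads))]
    mb = len(nodes)
    mt = len(nodes) + 1
    nodes = np.vstack([nodes, (nodes[a] + nodes[b]) / 2.0, (nodes[d_] + nodes[c]) / 2.0])
    base = 2 * lat.ncol * lat.nrow + 2
    c1 = (base + 2 * cid, (a, mb, mt, d_))
    c2 = (base + 2 * cid + 1, (mb, b, c, mt))

    def _insert_mid(ring, u, v, mid):
        """Insert `mid` on the (u, v) edge of a neighbouring cell, if present."""
        n = len(ring)
        for k in range(n):
            p, q = ring[k], ring[(k + 1) % n]
            if {p, q} == {u, v}:
                return ring[: k + 1] + (mid,) + ring[k + 1:]
        return ring

    out = []
    for ocid, ring in cells:
        if ocid == cid:
            continue
        ring = _insert_mid(ring, a, b, mb)  # neighbour sharing the bottom edge
        ring = _insert_mid(ring, d_, c, mt)  # neighbour sharing the top edge
        out.append((ocid, ring))
    cells = out + [c1, c2]
    return cells, nodes, [cid], None


def _build_side(
    lat: _Lattice,
    side: str,
    wing_type: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    fa_sd_um: float,
    directional_offset: np.ndarray,
    split_fraction: float,
) -> tuple[WingGeometry, list[int]]:
    """One wing from the shared true lattice plus side-specific noise."""
    nodes = lat.nodes_true.copy()
    sd = np.full(len(nodes), fa_sd_um, dtype=float)
    if config.fa_region == "distal":
        sd[lat.base_t > 0.5] *= config.fa_region_factor
    elif config.fa_region == "proximal":
        sd[lat.base_t <= 0.5] *= config.fa_region_factor
    if fa_sd_um > 0 or config.fa_region != "none":
        nodes = nodes + rng.normal(0.0, 1.0, size=nodes.shape) * sd[:, None]
    if config.fa_shape_sd > 0:
        nodes = nodes + rng.normal(0.0, config.fa_shape_sd * lat.pitch, size=nodes.shape)
    if side == "right":
        nodes = nodes + directional_offset

    cells = list(lat.cells)
    removed: list[int] = []
    eligible = side in config.count_perturb_sides
    if eligible and config.count_perturb_prob > 0 and rng.random() < config.count_perturb_prob:
        cells, nodes, removed, _ = _perturb_count(cells, lat, nodes, rng, config.count_perturb_mode)

    loop = _chain_boundary(_edges_of(cells))
    jids, jdeg = _junctions_from_cells(cells)

    # proximal/distal (Set 1/Set 2) labels, decided in the unmirrored frame
    split_x = split_fraction * lat.L
    labels = {}
    for cid, ring in cells:
        col = lat.cell_col.get(cid)
        if col is not None:
            xc = (lat.xs[col] + lat.xs[col + 1]) / 2.0
        else:  # merged/split cells: classify by current centroid position
            xc = nodes[list(ring)][:, 0].mean()
        labels[cid] = 1 if xc <= split_x else 2

    if side == "right":
        nodes = nodes * np.array([-1.0, 1.0])

    cell_polys = [CellPolygon(cid, nodes[list(ring)], set_label=labels[cid]) for cid, ring in cells]

    wing = WingGeometry(
        side=side,
        wing_type=wing_type,
        outline=nodes[loop],
        cells=cell_polys,
        junction_ids=jids,
        junction_xy=nodes[jids],
        junction_degree=jdeg,
    )
    return wing, removed


def generate_wing_pair(
    config: SyntheticConfig,
    individual_index: int = 0,
    wing_type: str = "front",
    length_um: float | None = None,
    fa_sd_um: float | None = None,
) -> tuple[WingGeometry, WingGeometry, GroundTruth]:
    """Generate one left/right wing pair plus its ground truth.

    The right wing is a mirrored copy of the shared true wing with its own
    independent noise; with all noise parameters zero it is an exact mirror
    of the left wing.  Degenerate tessellations are regenerated with a
    perturbed stream (up to 10 attempts).
    """
    config.validate()
    L = length_um if length_um is not None else config.outline_length_mm * 1000.0
    W = L / config.outline_aspect
    sd = fa_sd_um if fa_sd_um is not None else config.fa_position_sd_um
    stream_offset = {"front": 0, "hind": 100}[wing_type]

    last_err: Exception | None = None
    for attempt in range(10):
        rng = _rng_for(config, individual_index, stream=stream_offset + attempt)
        try:
            lat = _Lattice(L, W, config.cells_target, rng)
            offset = np.asarray(config.directional_offset_um, dtype=float)
            if config.antisymmetry_offset_um:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                offset = offset + np.array([sign * config.antisymmetry_offset_um, 0.0])
            left, removed_l = _build_side(lat, "left", wing_type, config, rng, sd, offset, config.split_fraction)
            right, removed_r = _build_side(lat, "right", wing_type, config, rng, sd, offset, config.split_fraction)
        except ValueError as err:  # degenerate tessellation -> retry
            last_err = err
            continue

        ids_l = {c.id for c in left.cells}
        ids_r = {c.id for c in right.cells}
        base_ids = {cid for cid, _ in lat.cells}
        common = sorted((ids_l & ids_r) & base_ids)
        jcommon = sorted(set(left.junction_ids) & set(right.junction_ids))
        gt = GroundTruth(
            individual=individual_index,
            wing_type=wing_type,
            length_um=L,
            width_um=W,
            cell_pairs=[(i, i) for i in common],
            junction_pairs=[(i, i) for i in jcommon],
            unmatched_cells_left=sorted(ids_l - set(common)),
            unmatched_cells_right=sorted(ids_r - set(common)),
            fa_region=config.fa_region,
            fa_position_sd_um=sd,
            directional_offset_um=tuple(np.asarray(config.directional_offset_um, dtype=float)),
        )
        return left, right, gt
    raise RuntimeError(f"degenerate tessellation after 10 attempts: {last_err}")


def generate_landmark_pair(
    config: SyntheticConfig,
    individual_index: int = 0,
    wing_type: str = "front",
    length_um: float | None = None,
    fa_sd_um: float | None = None,
) -> pd.DataFrame:
    """12 landmarks per side for one individual (long-format rows).

    Landmarks sit at fixed relative anchors on the true wing, pass through
    the same smooth deformation field as the lattice, and receive the same
    per-side positional jitter, so landmark-based FA tracks the junction
    FA channel.  Right-side landmarks are mirrored (x -> -x).
    """
    config.validate()
    L = length_um if length_um is not None else config.outline_length_mm * 1000.0
    W = L / config.outline_aspect
    sd = fa_sd_um if fa_sd_um is not None else config.fa_position_sd_um
    stream_offset = {"front": 0, "hind": 100}[wing_type]
    rng = _rng_for(config, individual_index, stream=stream_offset)
    lat = _Lattice(L, W, config.cells_target, rng)  # same deformation stream as the pair

    t, u = LANDMARK_ANCHORS[:, 0], LANDMARK_ANCHORS[:, 1]
    base = np.column_stack([t * L, u * (W / 2.0) * _half_width_profile(t)])
    # deformation field sampled at the anchors via the nearest lattice node
    from scipy.spatial import cKDTree

    grid0 = _undeformed_nodes(lat)
    _, idx = cKDTree(grid0).query(base)
    true_pts = base + (lat.nodes_true[idx] - grid0[idx])

    lm_rng = _rng_for(config, individual_index, stream=stream_offset + 50)
    offset = np.asarray(config.directional_offset_um, dtype=float)
    rows = []
    for side in ("left", "right"):
        pts = true_pts + lm_rng.normal(0.0, sd, size=true_pts.shape)
        if side == "right":
            pts = (pts + offset) * np.array([-1.0, 1.0])
        for k, (x, y) in enumerate(pts, start=1):
            rows.append(
                {"individual": individual_index, "side": side, "wing_type": wing_type,
                 "lm_index": k, "x": x, "y": y}
            )
    return pd.DataFrame(rows)


def _undeformed_nodes(lat: _Lattice) -> np.ndarray:
    """Node positions of the regular lattice before deformation."""
    xs = np.linspace(0.0, lat.L, lat.ncol + 1)
    ys = np.linspace(-lat.W / 2.0, lat.W / 2.0, lat.nrow + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def render_wing_image(wing: WingGeometry, scale_um_per_px: float, vein_width_px: int = 2) -> np.ndarray:
    """Rasterize a wing: dark veins on a white background (uint8 array).

    Veins are the union of all cell boundaries plus the outline.  The image
    y axis points down; anatomical +y maps to image top.  If the vein width
    approaches the smallest cell thickness, a warning is raised because such
    a cell may vanish from the raster (documented lossy case).
    """
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    if vein_width_px < 1:
        raise ValueError("vein width must be >= 1 px")
    from PIL import Image, ImageDraw

    pts = [wing.outline] + [c.vertices for c in wing.cells]
    allpts = np.vstack(pts)
    margin = 3 * vein_width_px * scale_um_per_px
    xmin, ymin = allpts.min(axis=0) - margin
    xmax, ymax = allpts.max(axis=0) + margin

    min_thick = min((2.0 * c.area / max(polygon_perimeter(c.vertices), 1e-12) for c in wing.cells), default=np.inf)
    if vein_width_px * scale_um_per_px >= min_thick:
        warnings.warn("vein width reaches the thinnest cell; that cell may vanish in the raster")

    def to_px(p: np.ndarray) -> list[tuple[float, float]]:
        x = (p[:, 0] - xmin) / scale_um_per_px
        y = (ymax - p[:, 1]) / scale_um_per_px
        return list(zip(x.tolist(), y.tolist()))

    w = int(np.ceil((xmax - xmin) / scale_um_per_px)) + 1
    h = int(np.ceil((ymax - ymin) / scale_um_per_px)) + 1
    img = Image.new("L", (w, h), 255)
    draw = ImageDraw.Draw(img)
    r = vein_width_px / 2.0
    seen: set[tuple] = set()
    for poly in pts:
        px = to_px(poly)
        n = len(px)
        for k in range(n):
            a, b = px[k], px[(k + 1) % n]
            key = (round(a[0], 3), round(a[1], 3), round(b[0], 3), round(b[1], 3))
            rkey = key[2:] + key[:2]
            if key in seen or rkey in seen:
                continue
            seen.add(key)
            draw.line([a, b], fill=0, width=vein_width_px)
            for p in (a, b):
                draw.ellipse([p[0] - r, p[1] - r, p[0] + r, p[1] + r], fill=0)
    return np.asarray(img, dtype=np.uint8)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def mesocosm_design(n_per_cell: int) -> pd.DataFrame:
    """Full 2x2 factorial (bti x hydrology), sexes balanced within cells."""
    rows = []
    for bti in (0, 1):
        for hyd in (0, 1):
            for k in range(n_per_cell):
                rows.append({"bti": bti, "hydrology": hyd, "sex": "f" if k % 2 == 0 else "m"})
    return pd.DataFrame(rows)


def insecticide_design(n_per_level: int, concentrations=(0.0, 0.0025, 0.01, 0.04)) -> pd.DataFrame:
    """Continuous-dose design in mg/L, sexes balanced within levels."""
    rows = []
    for c in concentrations:
        for k in range(n_per_level):
            rows.append({"concentration": float(c), "sex": "f" if k % 2 == 0 else "m"})
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """A generated cohort: covariate table, wing pairs, landmark table."""

    table: pd.DataFrame
    pairs: dict  # (individual, wing_type) -> (left, right, GroundTruth)
    landmarks: pd.DataFrame
    config: SyntheticConfig


def _factor_multiplier(effects: dict, factor: str, value, max_value: float) -> dict:
    """Per-parameter multipliers contributed by one factor at one level."""
    out = {}
    params = effects.get(factor, {})
    for param, mult in params.items():
        if isinstance(value, (bool, np.bool_)) or value in (0, 1):
            frac = float(value)
        else:
            frac = float(value) / max_value if max_value > 0 else 0.0
        out[param] = 1.0 + (mult - 1.0) * frac
    return out


def generate_cohort(
    config: SyntheticConfig,
    design: pd.DataFrame,
    with_wings: bool = True,
    with_landmarks: bool = True,
) -> Cohort:
    """Generate a stressor-structured cohort.

    ``design`` has one row per individual with factor columns (any of
    ``concentration``, ``bti``, ``hydrology``) and optionally ``sex``.
    ``config.effect_map`` maps factor name -> {parameter: multiplier at the
    active level (binary factors) or at the maximum dose (continuous)}.
    Parameters that can be scaled: ``outline_length_mm``,
    ``fa_position_sd_um``, ``wet_weight_mg``.
    """
    config.validate()
    if design is None:
        raise ValueError("a design table is required (it may be empty)")
    design = design.reset_index(drop=True)
    factor_cols = [c for c in design.columns if c != "sex"]
    max_vals = {c: (design[c].max() if len(design) else 1.0) for c in factor_cols}

    rows, pairs, lm_frames = [], {}, []
    for idx, drow in design.iterrows():
        rng = _rng_for(config, idx, stream=900)
        sex = drow.get("sex", "f" if idx % 2 == 0 else "m")

        mult = {"outline_length_mm": 1.0, "fa_position_sd_um": 1.0, "wet_weight_mg": 1.0}
        for fcol in factor_cols:
            for param, m in _factor_multiplier(config.effect_map, fcol, drow[fcol], max_vals[fcol]).items():
                mult[param] = mult.get(param, 1.0) * m

        size_mult = mult["outline_length_mm"] * (config.sex_effect if sex == "m" else 1.0)
        L_um = config.outline_length_mm * 1000.0 * size_mult * np.exp(rng.normal(0.0, config.size_cv))
        fa_sd = config.fa_position_sd_um * mult["fa_position_sd_um"]

        ww_median = config.wet_weight_mg * mult["wet_weight_mg"] * (
            config.male_weight_factor if sex == "m" else 1.0
        )
        wet_weight = ww_median * np.exp(rng.normal(0.0, config.wet_weight_cv))
        wet_weight_gain = config.wet_weight_gain_mg * np.exp(rng.normal(0.0, 0.3))
        days = int(rng.poisson(config.days_to_emergence_mean))

        row = {"individual": idx, "sex": sex, "wet_weight": wet_weight,
               "wet_weight_gain": wet_weight_gain, "days_to_emergence": days}
        for fcol in factor_cols:
            row[fcol] = drow[fcol]
        rows.append(row)

        for wt in config.wing_types:
            if with_wings:
                pairs[(idx, wt)] = generate_wing_pair(config, idx, wing_type=wt, length_um=L_um, fa_sd_um=fa_sd)
            if with_landmarks:
                lm = generate_landmark_pair(config, idx, wing_type=wt, length_um=L_um, fa_sd_um=fa_sd)
                lm["sex"] = sex
                lm_frames.append(lm)

    cols = ["individual", "sex", *factor_cols, "wet_weight", "wet_weight_gain", "days_to_emergence"]
    table = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    landmarks = pd.concat(lm_frames, ignore_index=True) if lm_frames else pd.DataFrame(
        columns=["individual", "side", "wing_type", "lm_index", "x", "y", "sex"]
    )
    return Cohort(table=table, pairs=pairs, landmarks=landmarks, config=config)
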