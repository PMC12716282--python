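"""Spatial localization of wing asymmetry.

Per-cell asymmetry values (shape differences between sister cells, or
sister-centroid distances) are anchored at cell positions, every wing is
superimposed into one common frame (rotation from a line fit through the
upper wing edge, translation of the centre of gravity to the origin), the
scattered values are linearly interpolated onto a 300 x 300 grid per wing,
grids are averaged per group, and group grids are subtracted
(treatment - control) and Gaussian-blurred (sigma = 10 grid cells) with
missing-node-aware normalization.  Positive difference values mean higher
asymmetry under the stressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import griddata

from .geometry import WingGeometry, polygon_centroid, resample_closed
from .pairing import AlignedPair, SisterMap

__all__ = [
    "AsymmetryGrid",
    "per_cell_asymmetry",
    "superimpose_common_frame",
    "common_extent",
    "build_group_grid",
    "difference_map",
    "save_grid",
    "load_grid",
    "render_heatmap",
]

GRID_SHAPE = (300, 300)
SHAPE_TRAITS = ("area", "length", "width", "circularity")
TRIMMED_TRAITS = ("circularity", "width")  # 5% tail exclusion applies to these


@dataclass
class AsymmetryGrid:
    """A trait-asymmetry matrix in the common wing frame for one group."""

    values: np.ndarray  # (300, 300), NaN where no wing contributes
    extent: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax), um
    trait: str
    group: str
    n_wings: int

    def __post_init__(self):
        if self.values.shape != GRID_SHAPE:
            raise ValueError(f"grid must be {GRID_SHAPE}, got {self.values.shape}")


def per_cell_asymmetry(
    aligned: AlignedPair,
    sister_map: SisterMap,
    trait: str,
    feats_l: pd.DataFrame | None = None,
    feats_r: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sister-cell asymmetry values anchored at mean sister positions.

    Shape traits yield the absolute left-right difference as a percentage of
    the reference side's value, averaged over both comparison directions;
    the ``centroid`` trait yields the Euclidean sister-centroid distance in
    um.  Returns ``(anchors, values)`` with anchors in the aligned-left
    frame (callers transform them into the common frame).
    """
    from .features import cell_feature_table

    if trait not in SHAPE_TRAITS and trait != "centroid":
        raise ValueError(f"unknown trait {trait!r}")
    if feats_l is None:
        feats_l = cell_feature_table(aligned.left)
    if feats_r is None:
        feats_r = cell_feature_table(aligned.right)
    pairs = sister_map.cell_pairs
    if not pairs:
        return np.empty((0, 2)), np.empty(0)
    li = [a for a, _ in pairs]
    ri = [b for _, b in pairs]
    pl = feats_l.loc[li, ["centroid_x", "centroid_y"]].to_numpy()
    pr = feats_r.loc[ri, ["centroid_x", "centroid_y"]].to_numpy()
    anchors = 0.5 * (pl + pr)
    if trait == "centroid":
        values = np.hypot(*(pl - pr).T)
    else:
        vl = feats_l.loc[li, trait].to_numpy()
        vr = feats_r.loc[ri, trait].to_numpy()
        d = np.abs(vl - vr)
        values = 50.0 * (d / vl + d / vr)  # mean of the two directional percents
    return anchors, values


def _upper_edge_angle(outline: np.ndarray) -> float:
    """Angle of the least-squares line through the upper-edge point set.

    The upper edge is operationalized as outline points within the top 10%
    of y, restricted to the middle 80% of the x range (the wing tip and
    base would otherwise dominate the fit).
    """
    pts = resample_closed(outline, 400)
    x, y = pts[:, 0], pts[:, 1]
    x0, x1 = x.min(), x.max()
    mid = (x >= x0 + 0.1 * (x1 - x0)) & (x <= x1 - 0.1 * (x1 - x0))
    if not mid.any():
        raise ValueError("degenerate outline: upper edge undefined")
    ymax, ymin = y[mid].max(), y.min()
    top = mid & (y >= ymax - 0.1 * (ymax - ymin))
    if top.sum() < 2:
        raise ValueError("degenerate outline: upper edge undefined")
    slope = np.polyfit(x[top], y[top], 1)[0]
    return float(np.arctan(slope))


def _canonical_angle(outline: np.ndarray) -> float:
    """Total rotation bringing a wing outline into the common frame.

    Rotation invariance requires a frame-independent construction: the
    outline is first brought into its principal-axis frame (the major axis
    horizontal, the wing tip pointing to a fixed side chosen from the sign
    of the third moment along the axis), and the upper-edge line fit is then
    applied once as a refinement inside that deterministic frame.
    """
    pts = resample_closed(outline, 400)
    d = pts - pts.mean(axis=0)
    cov = d.T @ d / len(d)
    w, vec = np.linalg.eigh(cov)
    if w[-1] <= w[0] * (1 + 1e-9):
        raise ValueError("degenerate outline: no principal axis")
    v = vec[:, -1]
    t = d @ v
    if np.mean(t**3) < 0:
        v = -v  # fix the tip side (positive skew -> +x) so flips cannot occur
    phi = -np.arctan2(v[1], v[0])
    c, s = np.cos(phi), np.sin(phi)
    rotated = d @ np.array([[c, -s], [s, c]]).T
    return phi - _upper_edge_angle(rotated)


def superimpose_common_frame(
    wings: list[WingGeometry], mirror_right: bool = True
) -> list[tuple[WingGeometry, callable]]:
    """Rotate and translate wings into one shared coordinate system.

    Right wings are mirrored first so all wings share the left orientation.
    Each wing is rotated about its centre of gravity until its upper edge is
    horizontal, then translated so the centre of gravity is at the origin.
    Returns ``(transformed_wing, transform)`` pairs; ``transform`` maps
    arbitrary points from the wing's (post-mirror) frame to the common frame.
    """
    if not wings:
        raise ValueError("need at least one wing")
    out = []
    for w in wings:
        ww = w.reflected_x() if (mirror_right and w.side == "right") else w
        cog = polygon_centroid(ww.outline)
        theta = _canonical_angle(ww.outline)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])

        def transform(points, _rot=rot, _cog=cog):
            return (np.asarray(points, dtype=float) - _cog) @ _rot.T

        out.append((ww.rotated(theta, about=cog).translated(-cog), transform))
    return out


def common_extent(point_sets: list[np.ndarray], pad: float = 0.02) -> tuple[float, float, float, float]:
    """Bounding box over all point sets, padded by a fraction of the span."""
    allp = np.vstack([p for p in point_sets if len(p)])
    xmin, ymin = allp.min(axis=0)
    xmax, ymax = allp.max(axis=0)
    dx, dy = (xmax - xmin) * pad, (ymax - ymin) * pad
    return (xmin - dx, xmax + dx, ymin - dy, ymax + dy)


def build_group_grid(
    wing_samples: list[tuple[np.ndarray, np.ndarray]],
    trait: str,
    group: str,
    extent: tuple[float, float, float, float],
    trim: bool | None = None,
    trim_quantile: float = 0.05,
    shape: tuple[int, int] = GRID_SHAPE,
) -> AsymmetryGrid:
    """Mean trait-asymmetry grid over all wings of one group.

    ``wing_samples`` holds one ``(points, values)`` pair per wing in the
    common frame.  Each wing is linearly (barycentric) interpolated onto the
    grid over its own convex hull; the group grid is the pointwise mean over
    wings, ignoring missing nodes.  When ``trim`` (default: on for
    circularity and width), values outside the pooled 5%-95% quantile band
    of the group are excluded before interpolation.
    """
    if trim is None:
        trim = trait in TRIMMED_TRAITS
    if sum(len(v) for _, v in wing_samples) < 3:
        raise ValueError("need at least 3 sample points in the group")
    if trim:
        pooled = np.concatenate([v for _, v in wing_samples if len(v)])
        lo, hi = np.quantile(pooled, [trim_quantile, 1.0 - trim_quantile])
        wing_samples = [
            (p[(v >= lo) & (v <= hi)], v[(v >= lo) & (v <= hi)]) for p, v in wing_samples
        ]

    xmin, xmax, ymin, ymax = extent
    gx, gy = np.meshgrid(
        np.linspace(xmin, xmax, shape[0]), np.linspace(ymin, ymax, shape[1]), indexing="ij"
    )
    layers = []
    for pts, vals in wing_samples:
        if len(vals) < 3:
            continue
        if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
            raise ValueError("all sample points of a wing are collinear")
        layers.append(griddata(pts, vals, (gx, gy), method="linear"))
    if not layers:
        raise ValueError("no wing had enough sample points to interpolate")
    stack = np.stack(layers)
    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        mean = np.nanmean(stack, axis=0)  # nodes outside every hull stay NaN
    return AsymmetryGrid(values=mean, extent=extent, trait=trait, group=group, n_wings=len(layers))


def difference_map(
    grid_treatment: AsymmetryGrid,
    grid_control: AsymmetryGrid,
    blur_sigma: float = 10.0,
) -> AsymmetryGrid:
    """Treatment minus control, Gaussian-blurred in grid-cell units.

    The blur is missing-node aware: the difference (with missing nodes as 0)
    and a validity mask are blurred separately and divided, so missing
    regions never fabricate low asymmetry.  Positive values mean the
    stressor increased local asymmetry.
    """
    if grid_treatment.extent != grid_control.extent:
        raise ValueError("grid extents do not match")
    diff = grid_treatment.values - grid_control.values
    valid = np.isfinite(diff)
    if blur_sigma > 0:
        v = np.where(valid, diff, 0.0)
        gv = ndimage.gaussian_filter(v, sigma=blur_sigma, mode="constant")
        gm = ndimage.gaussian_filter(valid.astype(float), sigma=blur_sigma, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(gm > 1e-6, gv / gm, np.nan)
        out[~valid & (gm <= 1e-6)] = np.nan
    else:
        out = np.where(valid, diff, np.nan)
    return AsymmetryGrid(
        values=out,
        extent=grid_treatment.extent,
        trait=grid_treatment.trait,
        group=f"{grid_treatment.group}-{grid_control.group}",
        n_wings=min(grid_treatment.n_wings, grid_control.n_wings),
    )


# ---------------------------------------------------------------------------
# persistence and rendering
# ---------------------------------------------------------------------------

def save_grid(grid: AsymmetryGrid, path_matrix, path_meta) -> None:
    """Plain-text matrix plus a JSON sidecar with extent and provenance."""
    import json

    np.savetxt(path_matrix, grid.values, fmt="%.8g")
    meta = {"extent": list(grid.extent), "trait": grid.trait, "group": grid.group,
            "n_wings": grid.n_wings}
    with open(path_meta, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_grid(path_matrix, path_meta) -> AsymmetryGrid:
    import json

    values = np.loadtxt(path_matrix)
    meta = json.load(open(path_meta))
    return AsymmetryGrid(values=values, extent=tuple(meta["extent"]), trait=meta["trait"],
                         group=meta["group"], n_wings=int(meta["n_wings"]))


def render_heatmap(grid: AsymmetryGrid, path, diverging: bool = False) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    v = grid.values.T  # (x, y) grid -> image rows are y
    if diverging:
        lim = np.nanmax(np.abs(v)) or 1.0
        im = ax.imshow(v, origin="lower", extent=grid.extent, cmap="RdBu_r",
                       vmin=-lim, vmax=lim, aspect="auto")
    else:
        im = ax.imshow(v, origin="lower", extent=grid.extent, cmap="magma", aspect="auto")
    fig.colorbar(im, ax=ax, label=grid.trait)
    ax.set_title(f"{grid.trait} asymmetry: {grid.group} (n={grid.n_wings})")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
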