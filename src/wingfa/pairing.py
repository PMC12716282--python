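"""Mirror, align and match left/right wings; compute the asymmetry inventory.

The pipeline for one individual's wing pair is:

1. :func:`align_pair` — reflect the right wing across the vertical axis,
   translate both wings to their outline centroids, and rotate the right
   wing to minimize the mean nearest-point distance between outlines.  No
   scaling is applied: size asymmetry is part of the signal.
2. :func:`match_sisters` — optimal one-to-one assignment of cells (and
   junctions) by centroid distance (Hungarian algorithm), gated at 25% of
   the wing length to rule out pathological cross-wing matches.
3. :func:`asymmetry_record` — the full variable inventory: trait NRMSE over
   sister cells (averaged over both comparison directions), mean matched
   distances, outline distance, count differences ("subtract values"), and
   pair-mean size variables.

:func:`screen_symmetry_type` implements the classical screening that must
precede an FA interpretation: a zero-mean test against directional
asymmetry and a normality/bimodality test against antisymmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .features import cell_feature_table, wing_features
from .geometry import WingGeometry, polygon_centroid, principal_extents, resample_closed

__all__ = [
    "AlignedPair",
    "SisterMap",
    "PairAsymmetryRecord",
    "SymmetryScreenReport",
    "align_pair",
    "match_sisters",
    "nrmse",
    "asymmetry_record",
    "pair_record",
    "screen_symmetry_type",
]

MATCH_GATE_FRACTION = 0.25  # unmatched beyond this fraction of wing length
OUTLINE_SAMPLES = 500  # arc-length-uniform outline resampling


@dataclass
class AlignedPair:
    left: WingGeometry
    right: WingGeometry  # reflected, translated, rotated into the left frame
    angle_rad: float
    residual_um: float  # symmetric mean nearest-point outline distance


@dataclass
class SisterMap:
    direction: str  # "L2R" | "R2L"
    cell_pairs: list[tuple[int, int]]  # (left id, right id)
    junction_pairs: list[tuple[int, int]]
    unmatched_cells_left: list[int] = field(default_factory=list)
    unmatched_cells_right: list[int] = field(default_factory=list)
    unmatched_junctions_left: list[int] = field(default_factory=list)
    unmatched_junctions_right: list[int] = field(default_factory=list)


@dataclass
class PairAsymmetryRecord:
    """All size and asymmetry variables of one left/right wing pair.

    Cell-level distances are in um; wing-level size variables in mm/mm^2;
    NRMSE values are dimensionless.  Directional quantities are the mean of
    both comparison directions (left/right and right/left).
    """

    nrmse_area: float
    nrmse_length: float
    nrmse_width: float
    nrmse_circularity: float
    mean_dist_junctions: float
    mean_dist_centroids: float
    mean_dist_outlines: float
    subtract_cells: int
    subtract_junctions: int
    wing_area: float  # mm^2, mean of sides
    wing_perimeter: float  # mm
    wing_length: float  # mm
    wing_width: float  # mm
    wing_area_diff: float  # mm^2, |L - R|
    wing_perimeter_diff: float  # mm
    n_cells: float  # mean of sides
    n_junctions: float
    n_matched_cells: int
    n_matched_junctions: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _mean_nearest(a: np.ndarray, b: np.ndarray, symmetric: bool = True) -> float:
    tb = cKDTree(b)
    d_ab = tb.query(a)[0].mean()
    if not symmetric:
        return float(d_ab)
    ta = cKDTree(a)
    return float(0.5 * (d_ab + ta.query(b)[0].mean()))


def align_pair(
    left: WingGeometry,
    right: WingGeometry,
    search_range_deg: float = 180.0,
    coarse_step_deg: float = 2.0,
    angle_tol_rad: float = 1e-4,
) -> AlignedPair:
    """Reflect, centre, and rotationally align a wing pair (no scaling).

    The rotation of the right wing minimizes the mean nearest-point
    distance between the two outlines, resampled to arc-length-uniform
    points; a coarse grid search brackets the optimum and golden-section
    refines it to ``angle_tol_rad``.  The zero angle is always evaluated,
    so an exact mirror pair aligns exactly.
    """
    lw = left.translated(-left.centroid)
    rw = right.reflected_x()
    rw = rw.translated(-rw.centroid)

    lo = resample_closed(lw.outline, OUTLINE_SAMPLES)
    ro = resample_closed(rw.outline, OUTLINE_SAMPLES)
    ltree = cKDTree(lo)

    def obj(theta: float) -> float:
        c, s = np.cos(theta), np.sin(theta)
        rot = ro @ np.array([[c, s], [-s, c]])  # == (R @ ro.T).T
        return float(ltree.query(rot)[0].mean())

    half = abs(search_range_deg)
    grid = np.deg2rad(np.arange(-half, half + 1e-9, coarse_step_deg))
    if 0.0 not in grid:
        grid = np.sort(np.append(grid, 0.0))
    vals = np.array([obj(t) for t in grid])
    k = int(np.argmin(vals))
    step = np.deg2rad(coarse_step_deg)
    res = optimize.minimize_scalar(
        obj, bounds=(grid[k] - step, grid[k] + step), method="bounded",
        options={"xatol": angle_tol_rad},
    )
    if not res.success:
        raise RuntimeError(f"alignment rotation search did not converge: {res.message}")
    candidates = [(obj(0.0), 0.0), (float(res.fun), float(res.x)), (float(vals[k]), float(grid[k]))]
    _, theta = min(candidates, key=lambda t: t[0])

    rw = rw.rotated(theta)
    ro_final = resample_closed(rw.outline, OUTLINE_SAMPLES)
    residual = _mean_nearest(lo, ro_final)
    return AlignedPair(left=lw, right=rw, angle_rad=float(theta), residual_um=residual)


def _assign(
    xy_l: np.ndarray, ids_l: np.ndarray, xy_r: np.ndarray, ids_r: np.ndarray, gate: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    if len(xy_l) == 0 or len(xy_r) == 0:
        return [], list(ids_l), list(ids_r)
    cost = cdist(xy_l, xy_r)
    ri, ci = linear_sum_assignment(cost)
    pairs, ml, mr = [], set(), set()
    for i, j in zip(ri, ci):
        if cost[i, j] <= gate:
            pairs.append((int(ids_l[i]), int(ids_r[j])))
            ml.add(i)
            mr.add(j)
    um_l = [int(ids_l[i]) for i in range(len(ids_l)) if i not in ml]
    um_r = [int(ids_r[j]) for j in range(len(ids_r)) if j not in mr]
    return pairs, um_l, um_r


def match_sisters(aligned: AlignedPair, direction: str = "L2R",
                  gate_fraction: float = MATCH_GATE_FRACTION) -> SisterMap:
    """Optimal one-to-one sister-cell and junction assignment."""
    if direction not in ("L2R", "R2L"):
        raise ValueError("direction must be 'L2R' or 'R2L'")
    left, right = aligned.left, aligned.right
    gate = gate_fraction * principal_extents(left.outline)[0]

    cl = np.array([polygon_centroid(c.vertices) for c in left.cells]).reshape(-1, 2)
    cr = np.array([polygon_centroid(c.vertices) for c in right.cells]).reshape(-1, 2)
    il = np.array([c.id for c in left.cells], dtype=int)
    ir = np.array([c.id for c in right.cells], dtype=int)
    cell_pairs, uml, umr = _assign(cl, il, cr, ir, gate)
    j_pairs, jul, jur = _assign(left.junction_xy, left.junction_ids,
                                right.junction_xy, right.junction_ids, gate)
    if direction == "R2L":
        cell_pairs = [(b, a) for a, b in cell_pairs]
        j_pairs = [(b, a) for a, b in j_pairs]
    return SisterMap(
        direction=direction,
        cell_pairs=cell_pairs,
        junction_pairs=j_pairs,
        unmatched_cells_left=uml,
        unmatched_cells_right=umr,
        unmatched_junctions_left=jul,
        unmatched_junctions_right=jur,
    )


def nrmse(values_ref, values_other) -> float:
    """Root-mean-square error normalized by the reference mean.

    One comparison direction only; callers average the two directions.
    An empty match set yields NaN with a warning.
    """
    ref = np.asarray(values_ref, dtype=float)
    oth = np.asarray(values_other, dtype=float)
    if ref.shape != oth.shape:
        raise ValueError("matched value lists must have equal length")
    if ref.size == 0:
        warnings.warn("empty match set: NRMSE undefined, emitting NaN")
        return float("nan")
    m = ref.mean()
    if m <= 0:
        raise ValueError("reference mean must be positive")
    return float(np.sqrt(np.mean((ref - oth) ** 2)) / m)


def _matched_values(feats_l: pd.DataFrame, feats_r: pd.DataFrame,
                    cell_pairs: list[tuple[int, int]], col: str) -> tuple[np.ndarray, np.ndarray]:
    if not cell_pairs:
        return np.empty(0), np.empty(0)
    li = [a for a, _ in cell_pairs]
    ri = [b for _, b in cell_pairs]
    return feats_l.loc[li, col].to_numpy(), feats_r.loc[ri, col].to_numpy()


def asymmetry_record(
    aligned: AlignedPair,
    map_lr: SisterMap,
    feats_l: pd.DataFrame | None = None,
    feats_r: pd.DataFrame | None = None,
) -> PairAsymmetryRecord:
    """Full asymmetry-variable inventory for one aligned pair.

    ``map_lr`` is the L2R sister map; the R2L direction reuses the same
    optimal assignment with the reference side swapped, and every
    directional quantity is reported as the mean of the two directions.
    """
    left, right = aligned.left, aligned.right
    if feats_l is None:
        feats_l = cell_feature_table(left)
    if feats_r is None:
        feats_r = cell_feature_table(right)

    out: dict[str, float] = {}
    for trait in ("area", "length", "width", "circularity"):
        vl, vr = _matched_values(feats_l, feats_r, map_lr.cell_pairs, trait)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore" if vl.size else "default")
            out[f"nrmse_{trait}"] = float(np.mean([nrmse(vl, vr), nrmse(vr, vl)])) if vl.size else float("nan")

    xl, xr = _matched_values(feats_l, feats_r, map_lr.cell_pairs, "centroid_x")
    yl, yr = _matched_values(feats_l, feats_r, map_lr.cell_pairs, "centroid_y")
    if len(map_lr.cell_pairs):
        mean_dist_centroids = float(np.hypot(xl - xr, yl - yr).mean())
    else:
        mean_dist_centroids = float("nan")

    if len(map_lr.junction_pairs):
        jl = {int(i): xy for i, xy in zip(left.junction_ids, left.junction_xy)}
        jr = {int(i): xy for i, xy in zip(right.junction_ids, right.junction_xy)}
        dj = [np.hypot(*(jl[a] - jr[b])) for a, b in map_lr.junction_pairs]
        mean_dist_junctions = float(np.mean(dj))
    else:
        mean_dist_junctions = float("nan")

    lo = resample_closed(left.outline, OUTLINE_SAMPLES)
    ro = resample_closed(right.outline, OUTLINE_SAMPLES)
    mean_dist_outlines = _mean_nearest(lo, ro)

    wf_l, wf_r = wing_features(left), wing_features(right)
    um2_mm2, um_mm = 1e-6, 1e-3
    return PairAsymmetryRecord(
        nrmse_area=out["nrmse_area"],
        nrmse_length=out["nrmse_length"],
        nrmse_width=out["nrmse_width"],
        nrmse_circularity=out["nrmse_circularity"],
        mean_dist_junctions=mean_dist_junctions,
        mean_dist_centroids=mean_dist_centroids,
        mean_dist_outlines=mean_dist_outlines,
        subtract_cells=abs(wf_l.n_cells - wf_r.n_cells),
        subtract_junctions=abs(wf_l.n_junctions - wf_r.n_junctions),
        wing_area=0.5 * (wf_l.area + wf_r.area) * um2_mm2,
        wing_perimeter=0.5 * (wf_l.perimeter + wf_r.perimeter) * um_mm,
        wing_length=0.5 * (wf_l.length + wf_r.length) * um_mm,
        wing_width=0.5 * (wf_l.width + wf_r.width) * um_mm,
        wing_area_diff=abs(wf_l.area - wf_r.area) * um2_mm2,
        wing_perimeter_diff=abs(wf_l.perimeter - wf_r.perimeter) * um_mm,
        n_cells=0.5 * (wf_l.n_cells + wf_r.n_cells),
        n_junctions=0.5 * (wf_l.n_junctions + wf_r.n_junctions),
        n_matched_cells=len(map_lr.cell_pairs),
        n_matched_junctions=len(map_lr.junction_pairs),
    )


def pair_record(left: WingGeometry, right: WingGeometry,
                search_range_deg: float = 180.0) -> PairAsymmetryRecord:
    """Convenience: align, match, and compute the record for a raw pair."""
    aligned = align_pair(left, right, search_range_deg=search_range_deg)
    smap = match_sisters(aligned)
    return asymmetry_record(aligned, smap)


@dataclass
class SymmetryScreenReport:
    n: int
    mean: float
    t_statistic: float
    mean_zero_p: float
    normality_statistic: float
    normality_p: float
    bimodality_coefficient: float
    directional_asymmetry: bool
    antisymmetry: bool


def _bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient; > 5/9 suggests a bimodal distribution."""
    n = len(x)
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)  # excess kurtosis
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def screen_symmetry_type(signed_differences, alpha: float = 0.05) -> SymmetryScreenReport:
    """Screen per-individual signed L-R differences of one trait.

    Directional asymmetry is flagged when the one-sample t-test rejects a
    zero mean; antisymmetry when the D'Agostino normality test rejects and
    the distribution is bimodal (bimodality coefficient > 5/9).
    """
    x = np.asarray(signed_differences, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("need at least 3 signed differences")
    t_stat, p_mean = stats.ttest_1samp(x, 0.0)
    if len(x) >= 8:
        k_stat, p_norm = stats.normaltest(x)
    else:  # D'Agostino needs n >= 8; fall back to Shapiro for tiny samples
        k_stat, p_norm = stats.shapiro(x)
    bc = _bimodality_coefficient(x) if len(x) > 3 else float("nan")
    return SymmetryScreenReport(
        n=len(x),
        mean=float(x.mean()),
        t_statistic=float(t_stat),
        mean_zero_p=float(p_mean),
        normality_statistic=float(k_stat),
        normality_p=float(p_norm),
        bimodality_coefficient=bc,
        directional_asymmetry=bool(p_mean < alpha),
        antisymmetry=bool(p_norm < alpha and bc > 5.0 / 9.0),
    )
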