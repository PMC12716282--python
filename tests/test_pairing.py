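"""Alignment, sister matching, NRMSE, asymmetry records and symmetry screening."""

import numpy as np
import pandas as pd
import pytest

from wingfa import SyntheticConfig, generate_wing_pair, nrmse, screen_symmetry_type
from wingfa.pairing import (
    AlignedPair,
    align_pair,
    asymmetry_record,
    match_sisters,
)
from wingfa.geometry import WingGeometry

from conftest import square_lattice_wing


# -- alignment --------------------------------------------------------------

def test_exact_mirror_aligns_to_zero(noise_free_pair):
    left, right, _ = noise_free_pair
    aligned = align_pair(left, right, search_range_deg=10)
    assert abs(aligned.angle_rad) < 1e-9
    assert aligned.residual_um < 1e-6


def test_rotated_mirror_is_recovered():
    cfg = SyntheticConfig(cells_target=80, fa_position_sd_um=0, fa_shape_sd=0,
                          count_perturb_prob=0, seed=6)
    left, right, _ = generate_wing_pair(cfg, 0)
    rot = right.rotated(np.deg2rad(-5.0), about=right.centroid)
    aligned = align_pair(left, rot, search_range_deg=15)
    # reflection flips the handedness of the rotation
    assert abs(abs(np.rad2deg(aligned.angle_rad)) - 5.0) < 0.1
    assert aligned.residual_um < 1.0


def test_disjoint_blobs_align_without_error():
    t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    a = WingGeometry("left", "front", np.column_stack([np.cos(t), np.sin(t)]) * 100)
    b = WingGeometry("right", "front", np.column_stack([np.cos(3 * t), np.sin(2 * t)]) * 80 + 500)
    aligned = align_pair(a, b)
    assert np.isfinite(aligned.residual_um)
    assert aligned.residual_um > 0


# -- matching ---------------------------------------------------------------

def test_identical_wings_match_perfectly(noise_free_pair):
    left, right, gt = noise_free_pair
    aligned = align_pair(left, right, search_range_deg=10)
    smap = match_sisters(aligned)
    assert len(smap.cell_pairs) == left.n_cells
    assert dict(smap.cell_pairs) == {a: b for a, b in gt.cell_pairs}
    assert not smap.unmatched_cells_left and not smap.unmatched_cells_right


def test_removed_cell_leaves_one_unmatched():
    cfg = SyntheticConfig(cells_target=60, fa_position_sd_um=0, fa_shape_sd=0,
                          count_perturb_prob=1.0, count_perturb_mode="merge",
                          count_perturb_sides=("right",), seed=3)
    left, right, _ = generate_wing_pair(cfg, 0)
    aligned = align_pair(left, right, search_range_deg=10)
    smap = match_sisters(aligned)
    # the right side lost one cell to a merge: exactly one left cell unmatched
    assert len(smap.cell_pairs) == right.n_cells
    assert len(smap.unmatched_cells_left) == 1


def test_jittered_matching_recovers_ground_truth(jittered_pair):
    left, right, gt = jittered_pair
    aligned = align_pair(left, right, search_range_deg=10)
    smap = match_sisters(aligned)
    truth = dict(gt.cell_pairs)
    hits = sum(1 for a, b in smap.cell_pairs if truth.get(a) == b)
    assert hits / len(truth) >= 0.99


# -- NRMSE ------------------------------------------------------------------

def test_nrmse_identical_lists_is_zero():
    assert nrmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_nrmse_hand_oracle():
    # ref=[1,2] vs [2,1]: RMSE=1, mean_ref=1.5 -> 2/3 in both directions
    assert nrmse([1, 2], [2, 1]) == pytest.approx(2 / 3)
    assert nrmse([2, 1], [1, 2]) == pytest.approx(2 / 3)


def test_nrmse_first_order_scaling():
    rng = np.random.default_rng(0)
    ref = rng.uniform(1, 3, 50)
    eps = 1e-4
    expected = eps * np.sqrt(np.mean(ref**2)) / ref.mean()
    assert nrmse(ref, ref * (1 + eps)) == pytest.approx(expected, rel=1e-6)


def test_nrmse_scale_invariance():
    rng = np.random.default_rng(1)
    a, b = rng.uniform(1, 2, 30), rng.uniform(1, 2, 30)
    assert nrmse(a, b) == pytest.approx(nrmse(7.3 * a, 7.3 * b), rel=1e-12)


def test_nrmse_empty_match_warns_nan():
    with pytest.warns(UserWarning, match="empty match"):
        assert np.isnan(nrmse([], []))


# -- asymmetry record -------------------------------------------------------

def _aligned_lattice_pair(shift=(0.0, 0.0)):
    """Frozen-alignment pair: right is the left lattice with junctions shifted."""
    left = square_lattice_wing(ncol=6, nrow=3, h=200.0)
    # attach junctions at interior nodes
    nodes = np.array([[i * 200.0, j * 200.0] for i in range(1, 6) for j in range(1, 3)])
    left.junction_ids = np.arange(len(nodes))
    left.junction_xy = nodes
    left.junction_degree = np.full(len(nodes), 4)
    import copy

    right = copy.deepcopy(left)
    right.side = "right"
    right.junction_xy = right.junction_xy + np.asarray(shift)
    return AlignedPair(left=left, right=right, angle_rad=0.0, residual_um=0.0)


def test_rigid_junction_shift_reads_back_exactly():
    aligned = _aligned_lattice_pair(shift=(10.0, 0.0))
    smap = match_sisters(aligned)
    rec = asymmetry_record(aligned, smap)
    assert rec.mean_dist_junctions == pytest.approx(10.0, abs=1e-9)
    assert rec.mean_dist_centroids == pytest.approx(0.0, abs=1e-9)


def test_subtract_values_are_absolute_count_differences():
    aligned = _aligned_lattice_pair()
    aligned.right.cells = aligned.right.cells[:-3]  # 18 vs 15 cells
    smap = match_sisters(aligned)
    rec = asymmetry_record(aligned, smap)
    assert rec.subtract_cells == 3
    assert rec.subtract_cells >= 0


def test_record_is_invariant_to_side_swap(jittered_pair):
    left, right, _ = jittered_pair
    a = align_pair(left, right, search_range_deg=10)
    ra = asymmetry_record(a, match_sisters(a))
    import dataclasses

    lsw = dataclasses.replace(right, side="left")
    rsw = dataclasses.replace(left, side="right")
    b = align_pair(lsw, rsw, search_range_deg=10)
    rb = asymmetry_record(b, match_sisters(b))
    # identical up to the rotation optimizer, whose nearest-point objective is
    # evaluated right-onto-left and so is not exactly swap-symmetric
    for name in ("nrmse_area", "nrmse_circularity", "mean_dist_junctions",
                 "mean_dist_centroids", "subtract_cells", "wing_area", "wing_length"):
        assert getattr(ra, name) == pytest.approx(getattr(rb, name), rel=5e-3), name


# -- symmetry-type screening ------------------------------------------------

def test_screen_requires_three_values():
    with pytest.raises(ValueError):
        screen_symmetry_type([0.1, -0.1])


def test_screen_null_is_mostly_clean():
    rng = np.random.default_rng(10)
    reps = 100
    da = sum(screen_symmetry_type(rng.normal(0, 1, 100)).directional_asymmetry for _ in range(reps))
    anti = sum(screen_symmetry_type(rng.normal(0, 1, 100)).antisymmetry for _ in range(reps))
    assert da / reps <= 0.10
    assert anti / reps <= 0.02


def test_screen_flags_directional_asymmetry():
    rng = np.random.default_rng(11)
    n, reps = 100, 100
    offset = 4.0 / np.sqrt(n)  # 4 sd/sqrt(n): theoretical t power ~0.98
    hits = sum(screen_symmetry_type(rng.normal(offset, 1, n)).directional_asymmetry
               for _ in range(reps))
    assert hits / reps > 0.9


def test_screen_flags_antisymmetry():
    rng = np.random.default_rng(12)
    n, reps = 100, 100
    hits = 0
    for _ in range(reps):
        x = rng.choice([-1.0, 1.0], n) + rng.normal(0, 0.3, n)
        hits += screen_symmetry_type(x).antisymmetry
    assert hits / reps > 0.9
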