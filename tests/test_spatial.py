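"""Spatial asymmetry maps: per-cell values, superimposition, gridding, blur."""

import numpy as np
import pytest

from wingfa import SyntheticConfig, generate_wing_pair
from wingfa.pairing import align_pair, match_sisters
from wingfa.spatial import (
    AsymmetryGrid,
    build_group_grid,
    common_extent,
    difference_map,
    per_cell_asymmetry,
    superimpose_common_frame,
)


@pytest.fixture(scope="module")
def aligned_noise_free(noise_free_pair):
    left, right, _ = noise_free_pair
    aligned = align_pair(left, right, search_range_deg=10)
    return aligned, match_sisters(aligned)


def test_symmetric_pair_has_zero_values(aligned_noise_free):
    aligned, smap = aligned_noise_free
    for trait in ("circularity", "centroid"):
        _, values = per_cell_asymmetry(aligned, smap, trait)
        assert np.allclose(values, 0.0, atol=1e-9)


def test_percent_difference_hand_oracle():
    """circularity 0.8 vs 0.72 -> mean(8/0.8, 8/0.72) percent = 10.56%."""
    import pandas as pd

    from wingfa.pairing import AlignedPair, SisterMap
    from conftest import square_lattice_wing

    left = square_lattice_wing(ncol=2, nrow=1, h=100.0)
    right = square_lattice_wing(ncol=2, nrow=1, h=100.0, side="right")
    aligned = AlignedPair(left, right, 0.0, 0.0)
    smap = SisterMap("L2R", cell_pairs=[(0, 0)], junction_pairs=[])
    feats = {"centroid_x": [50.0], "centroid_y": [50.0]}
    fl = pd.DataFrame({**feats, "circularity": [0.8]}, index=[0])
    fr = pd.DataFrame({**feats, "circularity": [0.72]}, index=[0])
    _, values = per_cell_asymmetry(aligned, smap, "circularity", fl, fr)
    expected = 100 * 0.5 * (0.08 / 0.8 + 0.08 / 0.72)
    assert values[0] == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(10.5555, abs=1e-3)


def test_centroid_trait_reads_rigid_offset():
    import pandas as pd

    from wingfa.pairing import AlignedPair, SisterMap
    from conftest import square_lattice_wing

    left = square_lattice_wing(ncol=2, nrow=1, h=100.0)
    aligned = AlignedPair(left, left, 0.0, 0.0)
    smap = SisterMap("L2R", cell_pairs=[(0, 0), (1, 1)], junction_pairs=[])
    fl = pd.DataFrame({"centroid_x": [50.0, 150.0], "centroid_y": [50.0, 50.0]}, index=[0, 1])
    fr = fl.copy()
    fr["centroid_x"] += 10.0
    _, values = per_cell_asymmetry(aligned, smap, "centroid", fl, fr)
    assert np.allclose(values, 10.0, atol=1e-12)


# -- superimposition --------------------------------------------------------

def test_canonical_wing_gets_identity_transform(noise_free_pair):
    left, _, _ = noise_free_pair
    (sup, transform), = superimpose_common_frame([left])
    # already horizontal: rotation ~0; translation = centroid removal
    probe = np.array([[0.0, 0.0], [1000.0, 0.0]])
    out = transform(probe)
    d = out[1] - out[0]
    angle = np.arctan2(d[1], d[0])
    assert abs(angle) < np.deg2rad(1.5)


def test_rotated_shifted_wing_is_recovered(noise_free_pair):
    left, _, _ = noise_free_pair
    (canon, _), = superimpose_common_frame([left])
    rot = left.rotated(np.deg2rad(7.0), about=left.centroid).translated([1234.0, -987.0])
    (sup, _), = superimpose_common_frame([rot])
    from scipy.spatial import cKDTree

    d, _ = cKDTree(canon.outline).query(sup.outline)
    assert np.median(d) < 0.002 * canon.length  # sub-0.2% of wing length


def test_mirrored_right_wings_overlay_left(noise_free_pair):
    left, right, _ = noise_free_pair
    out = superimpose_common_frame([left, right])
    from scipy.spatial import cKDTree

    a, b = out[0][0].outline, out[1][0].outline
    d, _ = cKDTree(a).query(b)
    assert d.mean() < 0.02 * left.length


# -- gridding ---------------------------------------------------------------

def _lattice_samples(value_fn, n=15):
    g = np.linspace(0.0, 1.0, n)
    pts = np.array([[x, y] for x in g for y in g])
    return pts, value_fn(pts)


def test_constant_field_grids_to_constant():
    pts, vals = _lattice_samples(lambda p: np.full(len(p), 3.7))
    grid = build_group_grid([(pts, vals)], "circularity", "g", (0, 1, 0, 1), trim=False)
    inside = np.isfinite(grid.values)
    assert inside.any()
    assert np.allclose(grid.values[inside], 3.7, atol=1e-9)


def test_linear_ramp_is_reproduced_exactly():
    pts, vals = _lattice_samples(lambda p: p[:, 0])
    grid = build_group_grid([(pts, vals)], "area", "g", (0, 1, 0, 1), trim=False)
    gx = np.linspace(0, 1, 300)
    inside = np.isfinite(grid.values)
    expected = np.broadcast_to(gx[:, None], grid.values.shape)
    assert np.allclose(grid.values[inside], expected[inside], atol=1e-6)


def test_trim_suppresses_extreme_contamination():
    rng = np.random.default_rng(0)
    pts, vals = _lattice_samples(lambda p: np.ones(len(p)))
    vals = vals.copy()
    bad = rng.choice(len(vals), size=len(vals) // 20, replace=False)
    vals[bad] *= 100.0
    clean = build_group_grid([(pts, np.ones(len(pts)))], "width", "g", (0, 1, 0, 1), trim=False)
    trimmed = build_group_grid([(pts, vals)], "width", "g", (0, 1, 0, 1), trim=True)
    m_clean = np.nanmean(clean.values)
    m_trim = np.nanmean(trimmed.values)
    assert abs(m_trim - m_clean) / m_clean < 0.05


def test_group_grid_is_permutation_invariant():
    rng = np.random.default_rng(3)
    wings = []
    for _ in range(4):
        pts = rng.uniform(0, 1, (40, 2))
        wings.append((pts, pts[:, 0] + rng.normal(0, 0.1, 40)))
    a = build_group_grid(wings, "area", "g", (0, 1, 0, 1), trim=False)
    b = build_group_grid(wings[::-1], "area", "g", (0, 1, 0, 1), trim=False)
    both = np.isfinite(a.values) & np.isfinite(b.values)
    assert np.allclose(a.values[both], b.values[both], atol=1e-9)
    assert np.array_equal(np.isfinite(a.values), np.isfinite(b.values))


def test_collinear_points_raise():
    pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
    with pytest.raises(ValueError, match="collinear"):
        build_group_grid([(pts, np.ones(10))], "area", "g", (0, 1, 0, 1), trim=False)


# -- difference maps --------------------------------------------------------

def _full_grid(values, group="g"):
    return AsymmetryGrid(values=values, extent=(0.0, 1.0, 0.0, 1.0), trait="area",
                         group=group, n_wings=5)


def test_identical_grids_difference_is_zero():
    v = np.random.default_rng(0).normal(size=(300, 300))
    d = difference_map(_full_grid(v, "t"), _full_grid(v.copy(), "c"))
    assert np.allclose(d.values, 0.0, atol=1e-12)


def test_extent_mismatch_raises():
    a = _full_grid(np.zeros((300, 300)))
    b = AsymmetryGrid(values=np.zeros((300, 300)), extent=(0, 2, 0, 1), trait="area",
                      group="c", n_wings=5)
    with pytest.raises(ValueError, match="extent"):
        difference_map(a, b)


def test_delta_spike_blurs_to_gaussian_profile():
    t = np.zeros((300, 300))
    t[150, 150] = 1.0
    d = difference_map(_full_grid(t, "t"), _full_grid(np.zeros((300, 300)), "c"), blur_sigma=10.0)
    ii, jj = np.meshgrid(np.arange(300), np.arange(300), indexing="ij")
    r2 = (ii - 150.0) ** 2 + (jj - 150.0) ** 2
    expected = np.exp(-r2 / (2 * 10.0**2)) / (2 * np.pi * 10.0**2)
    core = r2 < 40**2
    rms = np.sqrt(np.mean((d.values[core] - expected[core]) ** 2))
    assert rms < 0.02 * expected.max()


def test_distal_hotspot_is_localized():
    t = np.zeros((300, 300))
    t[200:260, 100:200] = 1.0  # hotspot in the distal (large-x) half
    d = difference_map(_full_grid(t, "t"), _full_grid(np.zeros((300, 300)), "c"), blur_sigma=10.0)
    v = d.values
    thr = np.nanquantile(v, 0.9)
    top = v >= thr
    mass = v[top].sum()
    distal = np.zeros_like(top)
    distal[150:, :] = True
    assert v[top & distal].sum() / mass >= 0.95


def test_missing_aware_blur_does_not_bleed_into_gaps():
    t = np.full((300, 300), np.nan)
    t[:, :150] = 2.0
    c = np.full((300, 300), np.nan)
    c[:, :150] = 1.0
    d = difference_map(_full_grid(t, "t"), _full_grid(c, "c"), blur_sigma=10.0)
    left_half = d.values[:, :120]
    assert np.allclose(left_half[np.isfinite(left_half)], 1.0, atol=1e-6)
    assert np.isnan(d.values[:, 200:]).all()


def test_common_extent_covers_all_points():
    a = np.array([[0.0, 0.0], [1.0, 1.0]])
    b = np.array([[-2.0, 0.5]])
    xmin, xmax, ymin, ymax = common_extent([a, b])
    assert xmin < -2.0 and xmax > 1.0 and ymin < 0.0 and ymax > 1.0
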