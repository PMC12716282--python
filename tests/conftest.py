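import numpy as np
import pytest

from wingfa import SyntheticConfig, generate_wing_pair
from wingfa.geometry import CellPolygon, WingGeometry


@pytest.fixture(scope="session")
def noise_free_pair():
    """Exact mirror pair: every downstream asymmetry metric must be zero."""
    cfg = SyntheticConfig(
        cells_target=120, fa_position_sd_um=0.0, fa_shape_sd=0.0,
        count_perturb_prob=0.0, seed=9,
    )
    return generate_wing_pair(cfg, 0)


@pytest.fixture(scope="session")
def jittered_pair():
    cfg = SyntheticConfig(
        cells_target=150, fa_position_sd_um=20.0, fa_shape_sd=0.0,
        count_perturb_prob=0.0, seed=4,
    )
    return generate_wing_pair(cfg, 0)


def square_lattice_wing(ncol=10, nrow=5, h=200.0, side="left"):
    """Plain rectangular lattice wing used as a combinatorial oracle fixture."""
    cells = []
    for i in range(ncol):
        for j in range(nrow):
            v = np.array([
                [i * h, j * h], [(i + 1) * h, j * h],
                [(i + 1) * h, (j + 1) * h], [i * h, (j + 1) * h],
            ])
            cells.append(CellPolygon(i * nrow + j, v))
    outline = np.array([[0, 0], [ncol * h, 0], [ncol * h, nrow * h], [0, nrow * h]], dtype=float)
    return WingGeometry(side, "front", outline, cells)


@pytest.fixture(scope="session")
def lattice_wing():
    return square_lattice_wing()
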