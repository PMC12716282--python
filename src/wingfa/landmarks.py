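"""Landmark-based Procrustes analysis with matching bilateral symmetry.

Wings are paired organs, so the matching-symmetry formulation is used: each
individual contributes two separate 12-landmark configurations (left, and
right reflected to the left orientation).  Generalized Procrustes analysis
(GPA) removes translation, scale and rotation; the per-individual left
minus right difference in shape space decomposes into a directional
component (the mean difference across individuals) and an individual
fluctuating-asymmetry (FA) component.  The FA score is the Procrustes
distance of the FA component from the mean symmetric shape, i.e. the
Euclidean norm of the component.

Sexes are fitted in separate GPAs (shape dimorphism would otherwise leak
into the asymmetry components); the resulting FA scores are pooled into one
response column for the model layer, which carries sex as a covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "GPAResult",
    "FAResult",
    "gpa",
    "fa_decomposition",
    "fa_scores",
    "read_tps",
    "write_tps",
    "read_landmark_csv",
    "write_landmark_csv",
]

N_LANDMARKS = 12


@dataclass
class LandmarkConfiguration:
    """One wing's ordered landmark set for one individual."""

    individual: object
    side: str  # "left" | "right"
    coords: np.ndarray  # (12, 2), um
    sex: str | None = None
    wing_type: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected {N_LANDMARKS} landmarks, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmarks contain non-finite coordinates")
        if len(np.unique(self.coords.round(9), axis=0)) != N_LANDMARKS:
            raise ValueError("duplicate landmark positions")


@dataclass
class GPAResult:
    aligned: np.ndarray  # (n, 12, 2), unit centroid size
    consensus: np.ndarray  # (12, 2)
    n_iterations: int
    converged: bool


@dataclass
class FAResult:
    consensus: np.ndarray  # mean symmetric shape (12, 2), unit centroid size
    directional_asymmetry: np.ndarray  # (12, 2) mean L-R vector
    fa_scores: pd.Series  # per individual, Procrustes distance units
    fa_components: dict  # individual -> (12, 2)


def _center_scale(shape: np.ndarray) -> np.ndarray:
    c = shape - shape.mean(axis=0)
    size = np.sqrt((c**2).sum())
    if size <= 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return c / size


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation (det = +1) minimizing ||src @ R - dst||."""
    u, _, vt = np.linalg.svd(src.T @ dst)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def gpa(
    configs: list[np.ndarray] | list[LandmarkConfiguration],
    reflect: list[bool] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes alignment of landmark configurations.

    Each configuration is translated to its centroid, scaled to unit
    centroid size, and iteratively rotated to the running consensus until
    the consensus change drops below ``tol``.  ``reflect[i]`` mirrors the
    i-th configuration (x -> -x) before fitting, used for right wings.
    """
    shapes = [c.coords if isinstance(c, LandmarkConfiguration) else np.asarray(c, dtype=float) for c in configs]
    if len(shapes) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if reflect is not None:
        shapes = [s * np.array([-1.0, 1.0]) if r else s for s, r in zip(shapes, reflect)]
    scaled = []
    for s in shapes:
        z = _center_scale(s)
        if np.linalg.matrix_rank(z.T @ z) < 2:
            raise ValueError("rank-deficient configuration: landmarks are collinear")
        scaled.append(z)
    x = np.stack(scaled)

    consensus = _center_scale(x[0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(x)):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus)
        new = _center_scale(x.mean(axis=0))
        delta = np.linalg.norm(new - consensus)
        consensus = new
        if delta < tol:
            converged = True
            break
    return GPAResult(aligned=x, consensus=consensus, n_iterations=it, converged=converged)


def fa_decomposition(aligned_by_individual: dict) -> FAResult:
    """Bilateral (matching) symmetry decomposition of aligned shapes.

    ``aligned_by_individual`` maps individual -> {"left": (12, 2),
    "right": (12, 2)} in the common GPA frame (right already reflected).
    Individuals missing a side are dropped with a warning.
    """
    complete = {}
    for ind, sides in aligned_by_individual.items():
        if "left" in sides and "right" in sides:
            complete[ind] = sides
        else:
            warnings.warn(f"individual {ind!r} is missing a side; dropped from FA")
    if not complete:
        raise ValueError("no individual has both sides")

    inds = list(complete)
    a = np.stack([complete[i]["left"] - complete[i]["right"] for i in inds])
    da = a.mean(axis=0)
    fa = a - da
    scores = pd.Series({i: float(np.linalg.norm(fa[k])) for k, i in enumerate(inds)}, name="fa_score")
    consensus = np.mean(
        [0.5 * (complete[i]["left"] + complete[i]["right"]) for i in inds], axis=0
    )
    return FAResult(
        consensus=consensus,
        directional_asymmetry=da,
        fa_scores=scores,
        fa_components={i: fa[k] for k, i in enumerate(inds)},
    )


def fa_scores(
    landmarks: pd.DataFrame,
    reflect_right: bool = True,
    by_sex: bool = True,
) -> pd.DataFrame:
    """Per-individual FA score per wing type from a long-format table.

    ``landmarks`` columns: individual, side, wing_type, lm_index, x, y and
    (if ``by_sex``) sex.  A separate GPA is fitted per sex and wing type;
    scores are pooled into one tidy output table.
    """
    required = {"individual", "side", "wing_type", "lm_index", "x", "y"}
    missing = required - set(landmarks.columns)
    if missing:
        raise ValueError(f"landmark table is missing columns: {sorted(missing)}")
    group_cols = ["wing_type"] + (["sex"] if by_sex and "sex" in landmarks.columns else [])

    out = []
    for keys, sub in landmarks.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        configs, meta = [], []
        for (ind, side), rows in sub.groupby(["individual", "side"]):
            rows = rows.sort_values("lm_index")
            configs.append(rows[["x", "y"]].to_numpy())
            meta.append((ind, side))
        if len(configs) < 2:
            warnings.warn(f"group {keys} has fewer than 2 configurations; skipped")
            continue
        reflect = [side == "right" and reflect_right for _, side in meta]
        res = gpa(configs, reflect=reflect)
        per_ind: dict = {}
        for (ind, side), shape in zip(meta, res.aligned):
            per_ind.setdefault(ind, {})[side] = shape
        fa = fa_decomposition(per_ind)
        for ind, score in fa.fa_scores.items():
            row = {"individual": ind, "fa_score": score}
            for col, val in zip(group_cols, keys):
                row[col] = val
            out.append(row)
    return pd.DataFrame(out, columns=["individual", *group_cols, "fa_score"])


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file (LM= blocks with ID= and optional side/sex).

    The ID line is parsed as ``individual[_side[_sex]]``; a missing side
    defaults to left.
    """
    configs = []
    lm, pts, meta = None, [], {}
    lines = [ln.strip() for ln in open(path) if ln.strip()]

    def flush():
        if lm is None:
            return
        ident = meta.get("ID", f"cfg{len(configs)}")
        parts = str(ident).split("_")
        individual = parts[0]
        side = parts[1] if len(parts) > 1 else "left"
        sex = parts[2] if len(parts) > 2 else None
        configs.append(LandmarkConfiguration(individual, side, np.array(pts), sex=sex))

    for ln in lines:
        if ln.upper().startswith("LM="):
            flush()
            lm, pts, meta = int(ln.split("=")[1]), [], {}
        elif "=" in ln:
            k, v = ln.split("=", 1)
            meta[k.upper()] = v
        else:
            pts.append([float(t) for t in ln.split()])
    flush()
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={len(c.coords)}\n")
            for x, y in c.coords:
                fh.write(f"{x:.6f} {y:.6f}\n")
            ident = f"{c.individual}_{c.side}" + (f"_{c.sex}" if c.sex else "")
            fh.write(f"ID={ident}\n")


def read_landmark_csv(path) -> pd.DataFrame:
    """Read the plain CSV dialect: individual, side, lm_index, x, y[, ...]."""
    df = pd.read_csv(path)
    required = {"individual", "side", "lm_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV is missing columns: {sorted(missing)}")
    return df


def write_landmark_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
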