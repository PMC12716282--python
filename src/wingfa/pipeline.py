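"""End-to-end orchestration: cohort -> asymmetry records -> stressor stats.

This is the layer the CLI and the examples drive.  It turns a generated (or
loaded) cohort of wing pairs into the tidy per-individual record table
(one row per individual x wing type) that feeds the GLM layer, carrying the
pair-asymmetry inventory, the landmark FA score, and the wing load.
"""

from __future__ import annotations

import logging
import warnings

import pandas as pd

from .landmarks import fa_scores
from .pairing import align_pair, asymmetry_record, match_sisters
from .spatial import (
    build_group_grid,
    common_extent,
    difference_map,
    per_cell_asymmetry,
    superimpose_common_frame,
)
from .stats import StressAnalysis, run_full_analysis
from .synthetic import Cohort

log = logging.getLogger("wingfa")

__all__ = ["records_from_cohort", "analyze_cohort", "spatial_maps_for_groups"]


def records_from_cohort(
    cohort: Cohort,
    search_range_deg: float = 15.0,
    max_failure_fraction: float = 0.5,
) -> pd.DataFrame:
    """Measure every wing pair of a cohort into one tidy record table.

    Pairs that fail to align or match are logged and skipped (partial
    failure isolation); the run aborts only if more than
    ``max_failure_fraction`` of the pairs fail.  For generator pairs, which
    are produced nearly aligned, a narrow rotation search range is enough
    and much faster than the full-circle search.
    """
    rows, failures = [], 0
    for (ind, wing_type), (left, right, _gt) in cohort.pairs.items():
        try:
            aligned = align_pair(left, right, search_range_deg=search_range_deg)
            smap = match_sisters(aligned)
            rec = asymmetry_record(aligned, smap)
        except Exception as err:  # noqa: BLE001 — isolate per-individual failures
            failures += 1
            log.warning("pair (%s, %s) failed: %s", ind, wing_type, err)
            continue
        row = {"individual": ind, "wing_type": wing_type, **rec.to_dict()}
        rows.append(row)
    if cohort.pairs and failures / len(cohort.pairs) > max_failure_fraction:
        raise RuntimeError(f"{failures}/{len(cohort.pairs)} wing pairs failed to analyze")

    records = pd.DataFrame(rows)
    if records.empty:
        return records
    records = records.merge(cohort.table, on="individual", how="left")
    records["wing_load"] = records["wet_weight"] / records["wing_area"]

    if len(cohort.landmarks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fa = fa_scores(cohort.landmarks)
        on = [c for c in ("individual", "wing_type", "sex") if c in fa.columns]
        records = records.merge(fa, on=on, how="left")
    return records


def analyze_cohort(
    cohort: Cohort,
    mode: str,
    search_range_deg: float = 15.0,
    **stats_kwargs,
) -> tuple[pd.DataFrame, StressAnalysis]:
    """Full pipeline: measurement records plus the fitted stressor models."""
    records = records_from_cohort(cohort, search_range_deg=search_range_deg)
    analysis = run_full_analysis(records, mode=mode, **stats_kwargs)
    return records, analysis


def spatial_maps_for_groups(
    cohort: Cohort,
    group_column: str,
    trait: str,
    wing_type: str = "front",
    search_range_deg: float = 15.0,
    blur_sigma: float = 10.0,
    min_wings: int = 3,
):
    """Group asymmetry grids and treatment-minus-control difference maps.

    Returns ``(grids, diffs)``: per-level :class:`AsymmetryGrid` objects and
    difference maps of every non-baseline level against the lowest level.
    Groups with fewer than ``min_wings`` contributing wings are skipped with
    a warning.
    """
    table = cohort.table.set_index("individual")
    samples_by_group: dict = {}
    for (ind, wt), (left, right, _gt) in cohort.pairs.items():
        if wt != wing_type:
            continue
        level = table.loc[ind, group_column]
        aligned = align_pair(left, right, search_range_deg=search_range_deg)
        smap = match_sisters(aligned)
        anchors, values = per_cell_asymmetry(aligned, smap, trait)
        # common-frame transform of the aligned-left wing carries the anchors
        (_, transform), = superimpose_common_frame([aligned.left])
        samples_by_group.setdefault(level, []).append((transform(anchors), values))

    extent = common_extent([p for group in samples_by_group.values() for p, _ in group])
    grids = {}
    for level, samples in sorted(samples_by_group.items()):
        if len(samples) < min_wings:
            warnings.warn(f"group {group_column}={level}: fewer than {min_wings} wings; skipped")
            continue
        grids[level] = build_group_grid(samples, trait=trait, group=f"{group_column}={level}",
                                        extent=extent)
    diffs = {}
    if grids:
        base_level = sorted(grids)[0]
        for level, grid in grids.items():
            if level != base_level:
                diffs[level] = difference_map(grid, grids[base_level], blur_sigma=blur_sigma)
    return grids, diffs
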