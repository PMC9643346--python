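"""End-to-end study pipeline: generate a cohort, measure it, plan access.

This is the programmatic equivalent of running ``generate-cohort``,
``measure``, ``plan-access`` and ``report`` in sequence, keeping everything
in memory.  All stages run from the voxel volumes alone (the ground-truth
parameters are returned only for validation against the measurements).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GeneratorConfig
from .morphometry import MorphometryRecord, measure_specimen
from .planning import (DEFAULT_DEPTH_LIMIT, DEFAULT_DRILL_RADIUS, HeatMap,
                       TrajectoryResult, aggregate_heatmap, build_dynamic_grid,
                       depth_report, evaluate_specimen, fit_rw_plane)
from .report import CohortTable, aggregate_table
from .synthetic import SpecimenParams, generate_cohort

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    params: list[SpecimenParams]
    records: list[MorphometryRecord]
    trajectories: list[list[TrajectoryResult]]
    heatmap: HeatMap
    depths: dict
    table: CohortTable
    spacing: float


def run_study(n: int = 10, seed: int = 0, spacing: float = 0.018,
              config: GeneratorConfig | None = None, threshold: float = 0.8,
              drill_radius: float = DEFAULT_DRILL_RADIUS,
              depth_limit: float = DEFAULT_DEPTH_LIMIT,
              progress: bool = False) -> StudyResult:
    """Run the full synthetic study on an n-specimen cohort.

    The stapedius occlusion is detected from the label map (label 6), not
    taken from the generator's ground truth, so the planning stage sees only
    what a real labelled scan would provide.
    """
    params_list, records, trajectories = [], [], []
    for i, (params, _, volume) in enumerate(generate_cohort(n, seed, config, spacing)):
        record = measure_specimen(volume, f"specimen_{i:02d}")
        plane, basis = fit_rw_plane(volume)
        membrane = volume.origin + np.argwhere(volume.grid == 4) * volume.spacing
        grid = build_dynamic_grid(plane, basis, membrane)
        results = evaluate_specimen(volume, grid, drill_radius=drill_radius,
                                    depth_limit=depth_limit)
        params_list.append(params)
        records.append(record)
        trajectories.append(results)
        if progress:
            print(f"specimen {i:02d}: length {record.rc_length:.3f} mm "
                  f"(truth {params.target_length:.3f})", flush=True)

    heatmap = aggregate_heatmap(trajectories, threshold=threshold)
    depths = depth_report(trajectories)
    table = aggregate_table(records)
    return StudyResult(params=params_list, records=records,
                       trajectories=trajectories, heatmap=heatmap,
                       depths=depths, table=table, spacing=spacing)
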