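"""Round-window access planning: dynamic grid, trajectory casting, heat map.

The planner fits the round-window membrane plane, lays a size-adjusted 4x4
grid over the membrane's in-plane bounding box (rows A-D superior to
inferior, columns 1-4 anterior to posterior), and casts a trephine-sized
capsule from each cell center along the inward membrane normal.  A cell
"hits" when the capsule first contacts canal tissue within the depth limit;
trajectories crossing the vestibulocochlear artery on the way are flagged
unsafe, and cells covered by the stapedius muscle are not evaluable.  Over a
cohort, per-cell hit frequencies give the probability heat map from which
cells are selected at a threshold (default 80 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CELL_LABELS, COL_LABELS, ROW_LABELS, inplane_basis
from .volume import LabelledVolume

__all__ = [
    "GridSpec", "TrajectoryResult", "HeatMap", "PlanningError",
    "fit_rw_plane", "build_dynamic_grid", "cast_trajectory",
    "evaluate_specimen", "aggregate_heatmap", "depth_report",
]

DEFAULT_DRILL_RADIUS = 0.2   # mm; trephine radius
DEFAULT_DEPTH_LIMIT = 4.0    # mm; from the 3-4 mm membrane-to-canal depth


class PlanningError(ValueError):
    """Raised for inputs the planner cannot process."""


@dataclass
class GridSpec:
    """Size-adjusted 4x4 grid on the membrane plane.

    ``cell_centers`` maps labels ("A1".."D4") to 3-D points on the plane;
    ``cell_size`` is the (anterior, superior) cell extent from the membrane's
    in-plane bounding box divided by 4.
    """

    center: np.ndarray
    normal: np.ndarray              # outward unit normal
    e_sup: np.ndarray
    e_ant: np.ndarray
    ant_range: tuple[float, float]  # in-plane bbox along e_ant (mm)
    sup_range: tuple[float, float]
    cell_centers: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def cell_size(self) -> tuple[float, float]:
        return ((self.ant_range[1] - self.ant_range[0]) / 4.0,
                (self.sup_range[1] - self.sup_range[0]) / 4.0)


@dataclass
class TrajectoryResult:
    cell: str
    hit_rc: bool
    depth_to_rc: float | None
    artery_collision: bool
    blocked_by_stapedius: bool
    evaluable: bool

    def __post_init__(self) -> None:
        assert (self.depth_to_rc is not None) == self.hit_rc
        if self.blocked_by_stapedius:
            assert not self.evaluable


@dataclass
class HeatMap:
    """Cohort 4x4 hit-frequency map with evaluability and safety flags.

    ``freq`` holds NaN for cells evaluable in zero specimens (reported as
    not-applicable, never as 0 %).
    """

    freq: np.ndarray          # 4x4 float, NaN = not applicable
    n_evaluable: np.ndarray   # 4x4 int
    n_hits: np.ndarray        # 4x4 int
    unsafe: np.ndarray        # 4x4 bool: any artery collision in cohort
    selected: frozenset[str]
    threshold: float
    n_specimens: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=list(ROW_LABELS), columns=list(COL_LABELS))


def _cell_index(cell: str) -> tuple[int, int]:
    return ROW_LABELS.index(cell[0]), COL_LABELS.index(cell[1])


# -- membrane plane and grid ---------------------------------------------------

def fit_rw_plane(volume: LabelledVolume) -> tuple[tuple[np.ndarray, np.ndarray],
                                                  tuple[np.ndarray, np.ndarray]]:
    """Fit the membrane plane; returns ((center, outward normal), (e_sup, e_ant)).

    Least-squares plane through label-4 voxel centers (the smallest principal
    component is the normal), oriented away from the perilymph centroid so it
    points out of the cochlea.
    """
    vox = np.argwhere(volume.grid == 4)
    if len(vox) < 10:
        raise PlanningError(
            f"membrane (label 4) has {len(vox)} voxels; at least 10 required")
    pts = volume.origin + vox * volume.spacing
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    normal = vt[-1]

    for ref_label in (2, 3):
        ref_vox = np.argwhere(volume.grid == ref_label)
        if len(ref_vox):
            ref_centroid = volume.origin + ref_vox.mean(axis=0) * volume.spacing
            if np.dot(normal, center - ref_centroid) < 0:
                normal = -normal
            break
    e_sup, e_ant = inplane_basis(normal)
    return (center, normal), (e_sup, e_ant)


def build_dynamic_grid(plane, basis, membrane_points: np.ndarray) -> GridSpec:
    """4x4 grid over the in-plane bounding box of projected membrane points."""
    center, normal = plane
    e_sup, e_ant = basis
    membrane_points = np.asarray(membrane_points, dtype=float)
    if membrane_points.ndim != 2 or len(membrane_points) == 0:
        raise PlanningError("membrane_points must be a non-empty (N, 3) array")
    rel = membrane_points - center
    a = rel @ e_ant
    s = rel @ e_sup
    ant_range = (float(a.min()), float(a.max()))
    sup_range = (float(s.min()), float(s.max()))
    if ant_range[1] - ant_range[0] <= 0 or sup_range[1] - sup_range[0] <= 0:
        raise PlanningError("membrane projection is degenerate (zero-area bounding box)")

    da = (ant_range[1] - ant_range[0]) / 4.0
    ds = (sup_range[1] - sup_range[0]) / 4.0
    centers = {}
    for i, row in enumerate(ROW_LABELS):          # A at the superior edge
        sc = sup_range[1] - (i + 0.5) * ds
        for j, col in enumerate(COL_LABELS):      # 1 at the anterior edge
            ac = ant_range[1] - (j + 0.5) * da
            centers[f"{row}{col}"] = center + ac * e_ant + sc * e_sup
    return GridSpec(center=center, normal=normal, e_sup=e_sup, e_ant=e_ant,
                    ant_range=ant_range, sup_range=sup_range, cell_centers=centers)


# -- trajectory casting --------------------------------------------------------

def _distance_field(volume: LabelledVolume, label: int, roi: tuple[slice, ...]):
    """EDT (mm) to the nearest voxel of ``label`` within an ROI, or None."""
    sub = volume.grid[roi]
    if not (sub == label).any():
        return None
    return ndimage.distance_transform_edt(sub != label, sampling=volume.spacing)


def _sample_field(field_arr, pts_idx):
    return ndimage.map_coordinates(field_arr, pts_idx.T, order=1, mode="nearest")


def _trajectory_fields(volume: LabelledVolume, origins: np.ndarray,
                       direction: np.ndarray, drill_radius: float,
                       depth_limit: float):
    """Distance fields (to canal and artery) on the swept region of interest."""
    sweep = np.concatenate([origins, origins + depth_limit * direction])
    margin = drill_radius + 3 * volume.spacing
    lo = volume.world_to_index(sweep.min(0) - margin)
    hi = volume.world_to_index(sweep.max(0) + margin)
    roi = tuple(slice(max(int(a), 0), min(int(b) + 1, dim))
                for a, b, dim in zip(lo, hi, volume.grid.shape))
    roi_origin = volume.origin + np.array([s.start for s in roi]) * volume.spacing
    return (_distance_field(volume, 3, roi), _distance_field(volume, 5, roi),
            roi_origin)


def cast_trajectory(volume: LabelledVolume, origin: np.ndarray,
                    direction: np.ndarray | None = None,
                    drill_radius: float = DEFAULT_DRILL_RADIUS,
                    depth_limit: float = DEFAULT_DEPTH_LIMIT,
                    *, cell: str = "", blocked_by_stapedius: bool = False,
                    _fields=None) -> TrajectoryResult:
    """Sweep a trephine capsule from ``origin`` along ``direction``.

    The capsule (cylinder of ``drill_radius`` with a hemispherical tip) is
    sampled at half-voxel steps; first contact with canal tissue (label 3)
    within ``depth_limit`` is a hit, with ``depth_to_rc`` the arc distance to
    that contact.  Artery contact (label 5) at or before the stopping depth
    is a collision.  ``direction`` defaults to the inward membrane normal
    when the volume carries a membrane; otherwise it must be given.
    """
    origin = np.asarray(origin, dtype=float)
    if not volume.contains(origin):
        raise PlanningError(f"trajectory origin {origin} outside volume bounds")
    if drill_radius <= 0:
        raise PlanningError("drill_radius must be positive")
    if direction is None:
        (_, n_out), _ = fit_rw_plane(volume)
        direction = -n_out
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    if blocked_by_stapedius:
        return TrajectoryResult(cell=cell, hit_rc=False, depth_to_rc=None,
                                artery_collision=False, blocked_by_stapedius=True,
                                evaluable=False)

    if _fields is None:
        _fields = _trajectory_fields(volume, origin[None, :], direction,
                                     drill_radius, depth_limit)
    d3, d5, roi_origin = _fields

    step = volume.spacing / 2.0
    ts = np.arange(0.0, depth_limit + step, step)
    ts = ts[ts <= depth_limit]
    pts = origin[None, :] + ts[:, None] * direction
    idx = (pts - roi_origin) / volume.spacing

    hit_rc, depth = False, None
    stop_i = len(ts) - 1
    if d3 is not None:
        prof3 = _sample_field(d3, idx)
        contact = np.nonzero(prof3 <= drill_radius)[0]
        if len(contact):
            hit_rc, stop_i = True, int(contact[0])
            depth = float(ts[stop_i])

    artery = False
    if d5 is not None:
        prof5 = _sample_field(d5, idx[:stop_i + 1])
        artery = bool(np.any(prof5 <= drill_radius))

    return TrajectoryResult(cell=cell, hit_rc=hit_rc, depth_to_rc=depth,
                            artery_collision=artery, blocked_by_stapedius=False,
                            evaluable=True)


def evaluate_specimen(volume: LabelledVolume, grid: GridSpec,
                      stapedius_cells: tuple[str, ...] | None = None,
                      drill_radius: float = DEFAULT_DRILL_RADIUS,
                      depth_limit: float = DEFAULT_DEPTH_LIMIT,
                      polar_offset_deg: float = 0.0,
                      azimuth_offset_deg: float = 0.0) -> list[TrajectoryResult]:
    """Cast one trajectory per grid cell; returns 16 results in label order.

    Stapedius-masked cells come from ``stapedius_cells`` if given, else from
    proximity of the cell center to stapedius tissue (label 6) in the volume.
    The insertion direction is the inward plane normal, optionally tilted by
    polar/azimuth offsets about the in-plane axes.
    """
    n_in = -grid.normal
    if polar_offset_deg or azimuth_offset_deg:
        polar = np.deg2rad(polar_offset_deg)
        az = np.deg2rad(azimuth_offset_deg)
        tilt_dir = np.cos(az) * grid.e_ant + np.sin(az) * grid.e_sup
        n_in = np.cos(polar) * n_in + np.sin(polar) * tilt_dir
        n_in /= np.linalg.norm(n_in)

    if stapedius_cells is None:
        stap_vox = np.argwhere(volume.grid == 6)
        stapedius_cells = ()
        if len(stap_vox):
            stap_pts = volume.origin + stap_vox * volume.spacing
            reach = 0.5 * max(grid.cell_size)
            stapedius_cells = tuple(
                c for c in CELL_LABELS
                if np.min(np.linalg.norm(stap_pts - grid.cell_centers[c], axis=1)) <= reach)

    all_centers = np.stack([grid.cell_centers[c] for c in CELL_LABELS])
    fields = _trajectory_fields(volume, all_centers, n_in, drill_radius, depth_limit)

    return [cast_trajectory(volume, grid.cell_centers[c], n_in,
                            drill_radius, depth_limit, cell=c,
                            blocked_by_stapedius=(c in stapedius_cells),
                            _fields=fields)
            for c in CELL_LABELS]


# -- cohort aggregation --------------------------------------------------------

def aggregate_heatmap(cohort_results: list[list[TrajectoryResult]],
                      threshold: float = 0.8) -> HeatMap:
    """Aggregate per-specimen trajectory results into the cohort heat map.

    Per-cell frequency = hits / evaluable specimens (NaN when never
    evaluable); a cell is unsafe if any specimen's trajectory collided with
    the artery; selected cells must be evaluable in every specimen, safe, and
    reach the canal with frequency >= threshold.
    """
    if not cohort_results:
        raise PlanningError("need at least one specimen's results")
    if not (0.0 < threshold <= 1.0):
        raise PlanningError(f"threshold must lie in (0, 1], got {threshold}")

    n_eval = np.zeros((4, 4), dtype=int)
    n_hits = np.zeros((4, 4), dtype=int)
    unsafe = np.zeros((4, 4), dtype=bool)
    for results in cohort_results:
        seen = {r.cell for r in results}
        if seen != set(CELL_LABELS):
            raise PlanningError("each specimen must report all 16 cells exactly once")
        for r in results:
            i, j = _cell_index(r.cell)
            if r.evaluable:
                n_eval[i, j] += 1
                n_hits[i, j] += int(r.hit_rc)
            if r.artery_collision:
                unsafe[i, j] = True

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_eval > 0, n_hits / np.maximum(n_eval, 1), np.nan)

    n_spec = len(cohort_results)
    selected = frozenset(
        c for c in CELL_LABELS
        if (lambda ij: n_eval[ij] == n_spec and not unsafe[ij]
            and freq[ij] >= threshold)(_cell_index(c)))
    return HeatMap(freq=freq, n_evaluable=n_eval, n_hits=n_hits, unsafe=unsafe,
                   selected=selected, threshold=threshold, n_specimens=n_spec)


def depth_report(cohort_results: list[list[TrajectoryResult]]) -> dict:
    """Min/median/max depth-to-canal over all hitting trajectories."""
    depths = [r.depth_to_rc for results in cohort_results for r in results
              if r.hit_rc and r.depth_to_rc is not None]
    if not depths:
        return {"n_hits": 0, "empty": True}
    return {
        "n_hits": len(depths),
        "empty": False,
        "min": float(np.min(depths)),
        "median": float(np.median(depths)),
        "max": float(np.max(depths)),
    }
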