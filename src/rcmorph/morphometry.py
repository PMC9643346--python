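"""Canal morphometry: centerline, length, station diameters, volumes.

Given a labelled volume, this module extracts the canal's medial axis by 3-D
thinning, measures its arc length, fits the modiolar axis, locates the 45°
and 90° cochlear-angle stations by unwrapped azimuth about that axis, and
estimates local diameters from the Euclidean distance transform (maximal
inscribed sphere, with a half-voxel boundary correction).  The result is one
cohort-table row per specimen: length, base/45°/90° diameters, canal volume,
and optionally the central nerve-space volume and bony-shell assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage, optimize
from skimage.morphology import skeletonize

from .volume import LABELS, LabelledVolume

__all__ = [
    "Centerline", "MorphometryRecord", "ModiolarAxis", "MorphometryError",
    "extract_canal_mask", "skeletonize_canal", "canal_length",
    "fit_modiolar_axis", "station_point", "local_diameter", "label_volume",
    "shell_assessment", "measure_specimen",
]

_SMOOTH_LENGTH_MM = 0.1      # moving-average span; >= 5 points at any spacing
_RESAMPLE_STEP_VOXELS = 1.0  # resampling step in voxel units, fixed


def _smooth_window(spacing: float) -> int:
    """Moving-average window in points: a fixed physical span (so the length
    estimate converges as spacing shrinks), never fewer than 5 points."""
    return max(5, int(round(_SMOOTH_LENGTH_MM / spacing)) | 1)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class MorphometryError(ValueError):
    """Raised for inputs the morphometry pipeline cannot measure."""


@dataclass
class Centerline:
    """Ordered canal-axis polyline with cumulative arc length (mm), basal first."""

    points: np.ndarray          # (N, 3) world mm
    cum_arclength: np.ndarray   # (N,) mm, cum_arclength[0] == 0
    basal_index: int = 0

    def length(self) -> float:
        return float(self.cum_arclength[-1])


@dataclass
class ModiolarAxis:
    point: np.ndarray
    direction: np.ndarray      # unit, oriented basal -> apical


@dataclass
class MorphometryRecord:
    """One specimen's cohort-table row (lengths mm, volumes mm³)."""

    specimen_id: str
    rc_length: float
    diam_base: float
    diam_45: float
    diam_90: float
    rc_volume: float
    nerve_space_volume: float | None = None
    shell_min_thickness: float | None = None   # µm
    dehiscent: bool | None = None


# -- mask extraction -----------------------------------------------------------

def extract_canal_mask(volume: LabelledVolume) -> np.ndarray:
    """Largest 26-connected canal component, closed with a 1-voxel radius."""
    raw = volume.grid == 3
    if not raw.any():
        raise MorphometryError("no canal voxels (label 3) in volume")
    lab, n = ndimage.label(raw, structure=_STRUCT26)
    if n > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        raw = lab == int(np.argmax(counts))
    # close within the component's bounding box only (cheap on large volumes)
    bbox = ndimage.find_objects(raw.astype(np.int8))[0]
    pad = tuple(slice(max(s.start - 2, 0), min(s.stop + 2, dim))
                for s, dim in zip(bbox, raw.shape))
    sub = ndimage.binary_closing(raw[pad], structure=_STRUCT6, iterations=1)
    out = raw.copy()
    out[pad] |= sub
    return out


# -- skeletonization -----------------------------------------------------------

def _skeleton_graph(skel: np.ndarray, spacing: float) -> nx.Graph:
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offsets = np.array([(dx, dy, dz)
                        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                        if (dx, dy, dz) > (0, 0, 0)])
    for off in offsets:
        for i, c in enumerate(coords):
            j = index.get(tuple(c + off))
            if j is not None:
                g.add_edge(i, j, weight=float(np.linalg.norm(off)) * spacing)
    return g


def _longest_endpoint_path(g: nx.Graph) -> list[int]:
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if not endpoints:
        raise MorphometryError(
            "skeleton has no endpoint nodes (cyclic or blob-like); input is not tubular")
    best = (-1.0, None, None)
    for src in endpoints:
        dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        for dst in endpoints:
            if dst in dist and dist[dst] > best[0]:
                best = (dist[dst], src, dst)
    _, src, dst = best
    return nx.dijkstra_path(g, src, dst, weight="weight")


def _inside(mask: np.ndarray, q: np.ndarray) -> bool:
    qi = np.rint(q).astype(int)
    if np.any(qi < 0) or np.any(qi >= np.asarray(mask.shape)):
        return False
    return bool(mask[tuple(qi)])


def _end_is_flat(mask: np.ndarray, end_pt: np.ndarray, tangent: np.ndarray,
                 r_vox: float, d_exit: float) -> bool:
    """Classify a tube end as flat-faced vs ball-capped by the mask
    cross-section area just inside the exit point (index units)."""
    if r_vox < 2.0 or d_exit <= 0:
        return False
    s_star = max(d_exit - 1.5, 0.25 * d_exit)
    center = end_pt + tangent * s_star
    reach = int(np.ceil(r_vox + 2))
    lo = np.maximum(np.floor(center - reach).astype(int), 0)
    hi = np.minimum(np.ceil(center + reach).astype(int) + 1,
                    np.asarray(mask.shape))
    if np.any(lo >= hi):
        return False
    idx = np.argwhere(mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]])
    if len(idx) == 0:
        return False
    rel = idx + lo - center
    axial = rel @ tangent
    lat2 = np.einsum("ij,ij->i", rel, rel) - axial ** 2
    count = int(np.count_nonzero((np.abs(axial) <= 0.75)
                                 & (lat2 <= (1.05 * r_vox) ** 2)))
    expected = np.pi * r_vox ** 2 * 1.5  # full-disc slab, 1.5 voxels thick
    return count >= 0.6 * expected


def _extend_to_mask_end(pts_idx: np.ndarray, mask: np.ndarray, edt: np.ndarray,
                        spacing: float) -> np.ndarray:
    """Extend flat-capped tube ends along their tangents to the mask boundary.

    Thinning retracts a tube's curve skeleton by roughly one local radius at
    a *flat* end face (the retained curve is the true medial axis; the lost
    length lives in the discarded end-sheet of the medial surface).  At a
    rounded (ball) cap the curve skeleton ideally reaches the cap center and
    extension by a radius would overshoot.  The two are distinguished by the
    mask cross-section area just inside the end: it stays a full disc at a
    flat face and collapses at a ball cap.  Flat ends extend to the mask
    exit; round ends
    extend by the walk-to-exit distance minus the local inscribed radius
    (zero for an ideal ball cap, positive when thinning has eroded a thin
    end beyond its cap center).
    """
    pts = pts_idx.astype(float)
    head, tail = [], []
    for end, sgn in ((0, -1), (-1, 1)):
        k = min(7, len(pts) - 1)
        tangent = (pts[end] - pts[end - sgn * k]).astype(float)
        norm = np.linalg.norm(tangent)
        r_vox = edt[tuple(pts_idx[end])] / spacing
        if norm == 0 or r_vox < 1.0:
            continue
        tangent /= norm
        d_exit = 0.0
        for s in np.arange(0.5, 1.5 * r_vox + 1.0, 0.5):
            if not _inside(mask, pts[end] + tangent * s):
                break
            d_exit = s
        flat = _end_is_flat(mask, pts[end], tangent, r_vox, d_exit)
        extend_by = d_exit if flat else min(max(d_exit - r_vox, 0.0), d_exit)
        if extend_by >= 0.5:
            q = pts[end] + tangent * extend_by
            (head if end == 0 else tail).append(q[None])
    return np.concatenate(head[::-1] + [pts] + tail, axis=0)


def skeletonize_canal(mask: np.ndarray, spacing: float,
                      origin: np.ndarray | None = None,
                      basal_hint: np.ndarray | None = None) -> Centerline:
    """Extract the canal centerline from a binary tube mask.

    3-D thinning -> 26-adjacency graph -> longest geodesic path between
    endpoints (side branches pruned) -> end-tangent extension to the mask
    boundary -> moving-average smoothing over a fixed ~0.1 mm span (at least
    5 points) -> uniform resampling at one voxel per step.  The basal endpoint is the one nearer ``basal_hint``
    (e.g. the round-window membrane centroid); fallback is the lower-z end.
    """
    if origin is None:
        origin = np.zeros(3)
    if not mask.any():
        raise MorphometryError("empty mask")

    bbox = ndimage.find_objects(mask.astype(np.int8))[0]
    pad = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                for s, dim in zip(bbox, mask.shape))
    sub = mask[pad]
    sub_origin = origin + np.array([s.start for s in pad]) * spacing

    skel = skeletonize(sub)
    if not skel.any():
        raise MorphometryError("thinning produced an empty skeleton")
    g = _skeleton_graph(skel, spacing)
    path = _longest_endpoint_path(g)
    coords = np.argwhere(skel)
    pts_idx = coords[path]

    edt = ndimage.distance_transform_edt(sub, sampling=spacing)
    pts = _extend_to_mask_end(pts_idx, sub, edt, spacing)

    smoothed = ndimage.uniform_filter1d(pts, _smooth_window(spacing), axis=0,
                                        mode="nearest")
    smoothed[0], smoothed[-1] = pts[0], pts[-1]  # keep the tube ends pinned
    world = sub_origin + smoothed * spacing

    seg = np.linalg.norm(np.diff(world, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    step = _RESAMPLE_STEP_VOXELS * spacing
    n_out = max(int(np.ceil(cum[-1] / step)) + 1, 2)
    s_new = np.linspace(0.0, cum[-1], n_out)
    world = np.stack([np.interp(s_new, cum, world[:, d]) for d in range(3)], axis=1)

    flip = False
    if basal_hint is not None:
        hint = np.asarray(basal_hint, dtype=float)
        flip = (np.linalg.norm(world[-1] - hint) < np.linalg.norm(world[0] - hint))
    else:
        flip = world[-1, 2] < world[0, 2]
    if flip:
        world = world[::-1].copy()

    seg = np.linalg.norm(np.diff(world, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(points=world, cum_arclength=cum, basal_index=0)


def canal_length(centerline: Centerline) -> float:
    """Total arc length (mm) of the centerline polyline."""
    if len(centerline.points) < 2:
        raise MorphometryError("centerline needs at least two points")
    return centerline.length()


# -- modiolar axis and angular stations ---------------------------------------

def _line_residuals(points: np.ndarray, p0: np.ndarray, d: np.ndarray) -> np.ndarray:
    w = points - p0
    proj = w - np.outer(w @ d, d)
    r = np.linalg.norm(proj, axis=1)
    return r - r.mean()


def fit_modiolar_axis(centerline: Centerline) -> ModiolarAxis:
    """Fit the helix axis: the line minimizing the variance of radial distance.

    Initialized from the mean tangent direction (the tangents of a helix lie
    on a cone about its axis), refined by nonlinear least squares.  Requires
    at least half a turn of total turning; straight centerlines are rejected.
    """
    pts = centerline.points
    if len(pts) < 10:
        raise MorphometryError("too few centerline points to fit an axis")
    tangents = np.diff(pts, axis=0)
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    turning = np.arccos(np.clip(np.sum(tangents[:-1] * tangents[1:], axis=1), -1, 1)).sum()
    if turning < np.pi:
        raise MorphometryError(
            f"centerline turns only {np.degrees(turning):.0f} deg (< 180 deg); "
            "not helical enough to define a modiolar axis")

    d0 = tangents.mean(axis=0)
    d0 /= np.linalg.norm(d0)
    c0 = pts.mean(axis=0)

    def unpack(x):
        theta, phi = x[3], x[4]
        d = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                      np.cos(theta)])
        return x[:3], d

    theta0 = np.arccos(np.clip(d0[2], -1, 1))
    phi0 = np.arctan2(d0[1], d0[0])
    x0 = np.concatenate([c0, [theta0, phi0]])
    sol = optimize.least_squares(lambda x: _line_residuals(pts, *unpack(x)), x0,
                                 method="lm", max_nfev=2000)
    p0, d = unpack(sol.x)
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    return ModiolarAxis(point=p0, direction=d / np.linalg.norm(d))


def unwrapped_azimuth(centerline: Centerline, axis: ModiolarAxis) -> np.ndarray:
    """Azimuth (degrees) of each centerline point about the axis, zeroed at
    the basal endpoint and unwrapped monotonically apically."""
    d = axis.direction
    w = centerline.points - axis.point
    w = w - np.outer(w @ d, d)
    ref = w[0] / np.linalg.norm(w[0])
    e2 = np.cross(d, ref)
    az = np.unwrap(np.arctan2(w @ e2, w @ ref))
    az -= az[0]
    if az[-1] < 0:
        az = -az
    return np.degrees(np.maximum.accumulate(az))


def station_point(centerline: Centerline, axis: ModiolarAxis,
                  angle_deg: float) -> int:
    """Index of the first centerline point reaching ``angle_deg`` of cochlear
    angle (azimuth about the modiolar axis from the basal end)."""
    az = unwrapped_azimuth(centerline, axis)
    if angle_deg < 0 or angle_deg > az[-1]:
        raise MorphometryError(
            f"angle {angle_deg} deg outside canal angular span [0, {az[-1]:.0f}] deg")
    return int(np.argmax(az >= angle_deg))


# -- diameters and volumes -----------------------------------------------------

def local_diameter(mask: np.ndarray, spacing: float, centerline: Centerline,
                   index: int, origin: np.ndarray | None = None,
                   edt: np.ndarray | None = None) -> float:
    """Maximal-inscribed-sphere diameter (mm) at a centerline point.

    Twice the Euclidean distance transform at the nearest voxel, averaged
    over a +/-3-point window along the centerline.  The transform measures to
    the nearest *background voxel center*, slightly beyond the true wall;
    half of that overshoot is cancelled by sub-voxel misplacement of the
    discrete centerline, so a half-voxel correction is applied to the
    diameter (quarter-voxel on the radius).
    """
    if origin is None:
        origin = np.zeros(3)
    if not (0 <= index < len(centerline.points)):
        raise MorphometryError(f"centerline index {index} out of range")
    if edt is None:
        edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    lo, hi = max(index - 3, 0), min(index + 4, len(centerline.points))
    window = centerline.points[lo:hi]
    idx = np.rint((window - origin) / spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(mask.shape) - 1)
    vals = edt[idx[:, 0], idx[:, 1], idx[:, 2]]
    if np.any(vals == 0):
        raise MorphometryError(
            "centerline point falls outside the mask; centerline and mask are misregistered")
    return float(2.0 * vals.mean() - spacing / 2.0)


def label_volume(volume: LabelledVolume, label: int) -> float:
    """Volume (mm³) of one label: voxel count x spacing³, exact."""
    if label not in LABELS:
        raise MorphometryError(f"label {label} not in scheme {sorted(LABELS)}")
    return float(np.count_nonzero(volume.grid == label) * volume.spacing ** 3)


def shell_assessment(volume: LabelledVolume) -> tuple[float, bool]:
    """Minimum bony-cover thickness (µm) over the canal, and dehiscence flag.

    Thickness: for canal surface voxels, distance through bone to the nearest
    exterior (non-bone, non-canal) voxel, minus one voxel of center-to-center
    offset.  Dehiscent: any canal voxel 6-adjacent to perilymph (label 2).
    """
    full = volume.grid
    if not (full == 3).any() or not (full == 1).any():
        raise MorphometryError("shell assessment needs both canal (3) and bone (1) labels")
    # the shell lives within a few voxels of the canal; work on that crop
    bbox = ndimage.find_objects((full == 3).astype(np.int8))[0]
    pad = tuple(slice(max(s.start - 25, 0), min(s.stop + 25, dim))
                for s, dim in zip(bbox, full.shape))
    grid = full[pad]
    canal = grid == 3
    solid = (grid == 1) | canal
    dist_to_exterior = ndimage.distance_transform_edt(solid, sampling=volume.spacing)
    surface = canal & ~ndimage.binary_erosion(canal, structure=_STRUCT6)
    min_d = float(dist_to_exterior[surface].min())
    thickness_um = max(min_d - volume.spacing, 0.0) * 1000.0
    touching_fluid = ndimage.binary_dilation(canal, structure=_STRUCT6) & (grid == 2)
    return thickness_um, bool(touching_fluid.any())


# -- full-record pipeline ------------------------------------------------------

def measure_specimen(volume: LabelledVolume,
                     specimen_id: str = "specimen") -> MorphometryRecord:
    """Measure one specimen's full cohort-table row from its label map."""
    mask_full = extract_canal_mask(volume)
    rw_vox = np.argwhere(volume.grid == 4)
    basal_hint = None
    if len(rw_vox):
        basal_hint = volume.origin + rw_vox.mean(axis=0) * volume.spacing

    # work on the canal's bounding box; the tube is surrounded by non-canal
    # voxels so the crop does not touch the distance transform
    bbox = ndimage.find_objects(mask_full.astype(np.int8))[0]
    pad = tuple(slice(max(s.start - 2, 0), min(s.stop + 2, dim))
                for s, dim in zip(bbox, mask_full.shape))
    mask = mask_full[pad]
    crop_origin = volume.origin + np.array([s.start for s in pad]) * volume.spacing

    cl = skeletonize_canal(mask, volume.spacing, origin=crop_origin,
                           basal_hint=basal_hint)
    length = canal_length(cl)
    axis = fit_modiolar_axis(cl)
    edt = ndimage.distance_transform_edt(mask, sampling=volume.spacing)

    diams = {}
    for angle in (0.0, 45.0, 90.0):
        i = station_point(cl, axis, angle)
        diams[angle] = local_diameter(mask, volume.spacing, cl, i,
                                      origin=crop_origin, edt=edt)

    nerve = label_volume(volume, 7) if (volume.grid == 7).any() else None
    shell_um = dehiscent = None
    if (volume.grid == 1).any():
        shell_um, dehiscent = shell_assessment(volume)

    return MorphometryRecord(
        specimen_id=specimen_id,
        rc_length=length,
        diam_base=diams[0.0],
        diam_45=diams[45.0],
        diam_90=diams[90.0],
        rc_volume=label_volume(volume, 3),
        nerve_space_volume=nerve,
        shell_min_thickness=shell_um,
        dehiscent=dehiscent,
    )
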